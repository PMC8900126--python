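"""Chain file readers/writers (JSON and flat CSV)."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .composition import STATE_CODES, STATE_NAMES, Chain
from .errors import SchemaError

JSON_SCHEMA_VERSION = 1


def chain_to_json(chain: Chain, path) -> None:
    """Write a chain as JSON: metadata plus per-monomer state-name triples."""
    doc = {
        "schema_version": JSON_SCHEMA_VERSION,
        "length": chain.n_monomers,
        "ds_cm": chain.ds_cm,
        "amide_fraction": chain.amide_fraction,
        "seed": chain.seed,
        "sequence": ["-".join(names) for names in chain.state_names()],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def _parse_state_triple(token: str, where: str) -> list[int]:
    parts = token.split("-")
    if len(parts) != 3:
        raise SchemaError(f"{where}: expected three '-'-joined states, got {token!r}")
    codes = []
    for p in parts:
        if p not in STATE_CODES:
            raise SchemaError(
                f"{where}: invalid state code {p!r} (expected one of {STATE_NAMES})"
            )
        codes.append(STATE_CODES[p])
    return codes


def chain_from_json(path) -> Chain:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON: {exc}") from exc
    for key in ("length", "ds_cm", "amide_fraction", "sequence"):
        if key not in doc:
            raise SchemaError(f"{path}: missing required field {key!r}")
    seq = doc["sequence"]
    if len(seq) != doc["length"]:
        raise SchemaError(
            f"{path}: declared length {doc['length']} != sequence length {len(seq)}"
        )
    codes = np.array(
        [_parse_state_triple(tok, f"{path}: sequence[{i}]") for i, tok in enumerate(seq)],
        dtype=np.int8,
    ).reshape(-1, 3)
    return Chain(
        codes=codes,
        ds_cm=float(doc["ds_cm"]),
        amide_fraction=float(doc["amide_fraction"]),
        seed=doc.get("seed"),
    )


CSV_HEADER = ["index", "pos2", "pos3", "pos6"]


def chain_to_csv(chain: Chain, path) -> None:
    """Write one monomer per row: index, pos2, pos3, pos6 state names."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for i, names in enumerate(chain.state_names()):
            writer.writerow([i, *names])


def chain_from_csv(path, ds_cm: float = 0.9, amide_fraction: float = 0.0) -> Chain:
    """Read the flat CSV form; sequence metadata is not stored in CSV."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != CSV_HEADER:
            raise SchemaError(f"{path}: bad header {header!r}, expected {CSV_HEADER}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 4:
                raise SchemaError(f"{path}:{lineno}: expected 4 fields, got {len(row)}")
            idx, *names = row
            try:
                idx = int(idx)
            except ValueError:
                raise SchemaError(f"{path}:{lineno}: index {row[0]!r} is not an integer")
            if idx != len(rows):
                raise SchemaError(f"{path}:{lineno}: out-of-order index {idx}")
            codes = []
            for col, name in zip(CSV_HEADER[1:], names):
                if name not in STATE_CODES:
                    raise SchemaError(
                        f"{path}:{lineno}: field {col}: invalid state {name!r}"
                    )
                codes.append(STATE_CODES[name])
            rows.append(codes)
    return Chain(
        codes=np.array(rows, dtype=np.int8).reshape(-1, 3),
        ds_cm=ds_cm,
        amide_fraction=amide_fraction,
    )
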