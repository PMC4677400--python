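"""Text-format helpers: FASTA round-trip and fixed-precision JSON."""

from __future__ import annotations

import json
import math
from typing import Dict

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(sequences: Dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _clean(obj, ndigits: int = 6):
    """Round floats, map non-finite values to null, recurse containers."""
    if isinstance(obj, dict):
        return {k: _clean(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v, ndigits) for v in obj]
    if isinstance(obj, bool):
        return obj
    if isinstance(obj, float):
        if not math.isfinite(obj):
            return None
        return round(obj, ndigits)
    if hasattr(obj, "item"):  # numpy scalars
        return _clean(obj.item(), ndigits)
    return obj


def dump_json(payload: dict, path, ndigits: int = 6) -> None:
    with open(path, "w") as fh:
        json.dump(_clean(payload, ndigits), fh, indent=2, sort_keys=True,
                  allow_nan=False)
        fh.write("\n")


def load_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
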