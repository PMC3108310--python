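"""Instance and report I/O.

Two plain-text instance formats:

* ``txt`` — one '0'/'1' string per line, uniform length, ``#`` comment
  lines and blank lines ignored;
* ``fasta`` — records whose sequences consist solely of '0'/'1'; headers
  are preserved as string labels (via Bio.SeqIO).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import Instance, InputError

FORMATS = ("txt", "fasta")


def _detect_format(path: Path) -> str:
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        return "fasta"
    return "txt"


def read_instance(path: str | Path, format: str | None = None) -> Instance:
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt not in FORMATS:
        raise InputError(f"unknown format {fmt!r}; choose from {FORMATS}")
    if fmt == "fasta":
        texts, labels = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            texts.append(str(rec.seq))
            labels.append(rec.id)
        if not texts:
            raise InputError(f"{path}: no FASTA records found")
        try:
            return Instance.from_texts(texts, labels)
        except InputError as e:
            raise InputError(f"{path}: {e}") from e
    texts = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if set(line) - {"0", "1"}:
                raise InputError(f"{path}:{lineno}: non-binary symbols in {line!r}")
            if texts and len(line) != len(texts[0]):
                raise InputError(
                    f"{path}:{lineno}: length {len(line)} differs from "
                    f"first string's {len(texts[0])}"
                )
            texts.append(line)
    if not texts:
        raise InputError(f"{path}: empty instance file")
    return Instance.from_texts(texts)


def write_instance(inst: Instance, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt == "fasta":
        labels = inst.labels or tuple(f"s{i + 1}" for i in range(inst.k))
        records = [
            SeqRecord(Seq(str(s)), id=label, description="")
            for s, label in zip(inst.strings, labels)
        ]
        SeqIO.write(records, str(path), "fasta")
        return
    with open(path, "w") as fh:
        for s in inst.strings:
            fh.write(str(s) + "\n")


def write_report(report: dict[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
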