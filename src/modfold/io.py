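"""Sequence input: FASTA or bare-line text over the extended alphabet."""

from __future__ import annotations

import io
from pathlib import Path


class SequenceInputError(ValueError):
    pass


def read_fasta_extended(source, convert_dna: bool = False) -> list[tuple[str, str]]:
    """Read sequences from FASTA or one-sequence-per-line text.

    ``source`` may be a path, a string of file content, or a text stream.
    Non-ACGU one-letter codes are preserved verbatim; with
    ``convert_dna=True`` the letter T is rewritten to U (do NOT enable
    this together with tRNA-database aliases, where T denotes
    5-methyluridine).
    """
    if isinstance(source, (str, Path)):
        p = Path(source)
        if isinstance(source, Path) or (len(str(source)) < 4096 and "\n" not in str(source) and p.is_file()):
            text = p.read_text()
        else:
            text = str(source)
    else:
        text = source.read()
    records: list[tuple[str, str]] = []
    lines = [ln.rstrip("\n\r") for ln in io.StringIO(text)]
    if any(ln.startswith(">") for ln in lines):
        if not lines[0].lstrip() or not any(
                ln.strip() for ln in lines):  # pragma: no cover - defensive
            raise SequenceInputError("empty FASTA input")
        stripped = "\n".join(ln for ln in lines if ln.strip())
        if not stripped.startswith(">"):
            raise SequenceInputError("sequence data before first FASTA header")
        from Bio import SeqIO
        for i, rec in enumerate(SeqIO.parse(io.StringIO(stripped), "fasta")):
            records.append((rec.id or f"seq_{i + 1}", str(rec.seq)))
    else:
        for ln in lines:
            if ln.strip():
                records.append((f"seq_{len(records) + 1}", ln.strip()))
    if not records or any(not seq for _, seq in records):
        raise SequenceInputError("no sequence records found in input")
    out = []
    for name, seq in records:
        seq = seq.replace(" ", "")
        if convert_dna:
            seq = seq.replace("T", "U").replace("t", "u")
        out.append((name, seq))
    return out
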