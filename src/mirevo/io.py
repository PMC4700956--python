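"""File-format helpers: FASTA, structure files, BED, TSV tables.

The structure file is FASTA-like: a header line carrying the precursor
metadata as ``key=value`` tokens, then the sequence line, then the
dot-bracket line, e.g.::

    >hp1 mature=88:110 star=10:32 arm=3p energy=-30.0
    ACGU...
    (((( ...

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMP = str.maketrans("ACGTUacgtuNn", "TGCAAtgcaaNn")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet; U complements to A)."""
    return seq.translate(_COMP)[::-1]


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered ``{id: sequence}`` dict (uppercased)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path, records: dict[str, str] | Iterable[tuple[str, str]], descriptions=None):
    items = records.items() if hasattr(records, "items") else records
    descriptions = descriptions or {}
    recs = [
        SeqRecord(Seq(seq), id=name, description=descriptions.get(name, ""))
        for name, seq in items
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_structures(path, precursors):
    """Write precursor records (sequence + dot-bracket + spans) to a file."""
    with open(path, "w") as fh:
        for p in precursors:
            energy = getattr(p, "fold_energy", float("nan"))
            fh.write(
                f">{p.id} mature={p.mature_span[0]}:{p.mature_span[1]} "
                f"star={p.star_span[0]}:{p.star_span[1]} arm={'5p' if p.arm == 'five_prime' else '3p'} "
                f"energy={energy}\n{p.sequence}\n{p.structure}\n"
            )


def read_structures(path):
    """Read a structure file back into ``Precursor`` records."""
    from .hairpin_discovery import Precursor

    out = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    for i in range(0, len(lines), 3):
        header, seq, struct = lines[i], lines[i + 1], lines[i + 2]
        if not header.startswith(">"):
            raise ValueError(f"malformed structure file near {header!r}")
        fields = header[1:].split()
        pid = fields[0]
        meta = dict(tok.split("=", 1) for tok in fields[1:])
        mat = tuple(int(x) for x in meta["mature"].split(":"))
        star = tuple(int(x) for x in meta["star"].split(":"))
        arm = "five_prime" if meta.get("arm", "3p") == "5p" else "three_prime"
        out.append(
            Precursor(
                id=pid,
                sequence=seq,
                structure=struct,
                mature_span=mat,
                star_span=star,
                arm=arm,
                fold_energy=float(meta.get("energy", "nan")),
            )
        )
    return out


def write_bed(path, rows):
    """Write BED6 rows: (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed(path):
    rows = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith(("#", "track", "browser")):
                continue
            f = ln.split("\t")
            rows.append(
                (f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else ".",
                 f[4] if len(f) > 4 else ".", f[5] if len(f) > 5 else "+")
            )
    return rows


def ensure_dir(path):
    os.makedirs(path, exist_ok=True)
    return path
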