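"""Readers/writers for standard formats, coordinate conventions and small utilities.

All genomic intervals are held internally as 0-based half-open ``[start, end)``;
conversion to/from the 1-based closed GFF3 convention happens only at the I/O
boundary.  Sequences are stored uppercase over the alphabet ``ACGTN`` —
IUPAC ambiguity letters are folded to ``N`` (and counted) rather than rejected,
so that downstream k-mer stages can skip them deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

log = logging.getLogger("subkit")

#: Mbp of double-stranded DNA per picogram (Doležel conversion, 978 Mbp/pg).
MBP_PER_PG = 978.0

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class GenomeSet:
    """Named scaffolds with sequence; the universe all coordinates refer to.

    Scaffold names are unique and insertion-ordered.  Sequences are uppercase
    ACGTN strings.
    """

    def __init__(self, scaffolds: Mapping[str, str] | None = None):
        self.scaffolds: dict[str, str] = {}
        if scaffolds:
            for name, seq in scaffolds.items():
                self.add(name, seq)

    def add(self, name: str, seq: str) -> None:
        if name in self.scaffolds:
            raise ValueError(f"duplicate scaffold name: {name!r}")
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"scaffold {name!r} contains letters outside ACGTN: {sorted(bad)}")
        self.scaffolds[name] = seq

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.scaffolds.items()}

    def __len__(self) -> int:
        return len(self.scaffolds)

    def __contains__(self, name: str) -> bool:
        return name in self.scaffolds

    def __getitem__(self, name: str) -> str:
        return self.scaffolds[name]

    def names(self) -> list[str]:
        return list(self.scaffolds)


@dataclass
class Feature:
    """A located annotation (gene, TE, LTR element/terminal repeat, exchange segment).

    Coordinates are 0-based half-open on the named scaffold.
    """

    scaffold: str
    start: int
    end: int
    strand: str = "."
    kind: str = "gene"
    id: str = ""
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end}) for {self.id!r}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PafRecord:
    """One minimap2-style PAF alignment line (columns 1-12; tags ignored)."""

    query: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    target: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    alen: int
    mapq: int = 255

    def __post_init__(self):
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise ValueError(f"bad query interval in PAF record {self.query}->{self.target}")
        if not (0 <= self.tstart < self.tend <= self.tlen):
            raise ValueError(f"bad target interval in PAF record {self.query}->{self.target}")
        if self.nmatch > self.alen:
            raise ValueError("nmatch exceeds alignment length")


@dataclass
class FcmSample:
    """A flow-cytometry measurement against an internal size standard.

    ``fl2a_*`` are propidium-iodide fluorescence areas; ``standard_2c`` is the
    standard's known 2C DNA content in picograms.
    """

    fl2a_sample: float
    fl2a_standard: float
    standard_2c: float
    conversion: float = MBP_PER_PG

    def __post_init__(self):
        for name in ("fl2a_sample", "fl2a_standard", "standard_2c", "conversion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeSet:
    """Load a FASTA file into a :class:`GenomeSet`.

    Lowercase is folded to uppercase; any letter outside ACGTN becomes ``N``
    (the substitution count is logged).  Duplicate record names and empty
    files are hard errors.
    """
    path = Path(path)
    genome = GenomeSet()
    name = None
    chunks: list[str] = []
    n_subst = 0

    def _flush():
        nonlocal n_subst
        if name is None:
            return
        seq = "".join(chunks).upper()
        clean = []
        for ch in seq:
            if ch in _VALID:
                clean.append(ch)
            else:
                clean.append("N")
                n_subst += 1
        genome.add(name, "".join(clean))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line)
    _flush()
    if len(genome) == 0:
        raise ValueError(f"{path}: empty FASTA file")
    if n_subst:
        log.info("read_fasta %s: folded %d non-ACGTN letters to N", path.name, n_subst)
    return genome


def write_fasta(genome: GenomeSet, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.scaffolds.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 / BED features
# ---------------------------------------------------------------------------

def read_features(
    path: str | Path,
    dialect: str,
    lengths: Mapping[str, int] | None = None,
) -> list[Feature]:
    """Read gene/TE annotations from GFF3 (1-based closed) or BED (0-based half-open).

    Coordinates are normalized to the internal 0-based half-open convention:
    a GFF3 record ``start=s, end=e`` becomes ``(s-1, e)``.  Records that are
    empty after normalization are rejected with a warning; if scaffold
    ``lengths`` are supplied, features extending past the scaffold end are
    clipped (with a warning).
    """
    if dialect not in ("gff3", "bed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    feats: list[Feature] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if dialect == "gff3":
                if len(cols) < 9:
                    log.warning("%s:%d: short GFF3 line skipped", path, ln)
                    continue
                scaf, _src, kind, s, e, _score, strand, _frame, attr_col = cols[:9]
                start, end = int(s) - 1, int(e)
                attrs = {}
                for item in attr_col.split(";"):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        attrs[k.strip()] = v.strip()
                fid = attrs.get("ID", f"{kind}:{scaf}:{start}")
            else:
                if len(cols) < 3:
                    log.warning("%s:%d: short BED line skipped", path, ln)
                    continue
                scaf, s, e = cols[:3]
                start, end = int(s), int(e)
                fid = cols[3] if len(cols) > 3 else f"{scaf}:{start}"
                strand = cols[5] if len(cols) > 5 else "."
                kind = "gene"
                attrs = {}
            if lengths is not None and scaf in lengths and end > lengths[scaf]:
                log.warning("%s:%d: feature %s clipped to scaffold end", path, ln, fid)
                end = lengths[scaf]
            if end <= start:
                log.warning("%s:%d: empty interval after normalization, record rejected", path, ln)
                continue
            if strand not in ("+", "-"):
                strand = "."
            feats.append(Feature(scaf, start, end, strand, kind, fid, attrs))
    return feats


def write_features(feats: Iterable[Feature], path: str | Path, dialect: str = "gff3") -> None:
    """Write features back out, undoing the coordinate normalization for GFF3."""
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
            for f in feats:
                attrs = ";".join([f"ID={f.id}"] + [f"{k}={v}" for k, v in f.attrs.items()])
                fh.write(
                    f"{f.scaffold}\tsubkit\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
                )
        elif dialect == "bed":
            for f in feats:
                fh.write(f"{f.scaffold}\t{f.start}\t{f.end}\t{f.id}\t0\t{f.strand}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------

def read_paf(path: str | Path) -> list[PafRecord]:
    """Read minimap2 PAF, columns 1-12 (cg/extra tags ignored)."""
    recs = []
    with open(path) as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 12:
                continue
            recs.append(
                PafRecord(
                    query=cols[0], qlen=int(cols[1]), qstart=int(cols[2]), qend=int(cols[3]),
                    strand=cols[4],
                    target=cols[5], tlen=int(cols[6]), tstart=int(cols[7]), tend=int(cols[8]),
                    nmatch=int(cols[9]), alen=int(cols[10]), mapq=int(cols[11]),
                )
            )
    return recs


def write_paf(recs: Iterable[PafRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in recs:
            fh.write(
                f"{r.query}\t{r.qlen}\t{r.qstart}\t{r.qend}\t{r.strand}\t"
                f"{r.target}\t{r.tlen}\t{r.tstart}\t{r.tend}\t{r.nmatch}\t{r.alen}\t{r.mapq}\n"
            )


# ---------------------------------------------------------------------------
# Flow cytometry genome-size arithmetic
# ---------------------------------------------------------------------------

def estimate_2c(sample: FcmSample) -> float:
    """2C DNA content (pg) by linear interpolation against the internal standard."""
    return sample.standard_2c * sample.fl2a_sample / sample.fl2a_standard


def haploid_size_mbp(two_c: float, conversion: float = MBP_PER_PG) -> float:
    """Haploid (1C) genome size in Mbp from a 2C value in picograms."""
    if two_c <= 0:
        raise ValueError("2C value must be strictly positive")
    if conversion <= 0:
        raise ValueError("conversion must be strictly positive")
    return two_c / 2.0 * conversion
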