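"""Coding-sequence IO, validation and run configuration.

The pipeline's atomic record is an in-frame CDS with its derived peptide.
Records with ambiguous bases, internal stops or out-of-frame lengths are
rejected on input (NG86 counting is undefined on ambiguous codons); a
terminal stop codon is silently stripped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._codons import STOP_CODONS

logger = logging.getLogger("paleoks")

_VALID_NT = frozenset("ACGT")


class InvalidCDSError(ValueError):
    """Raised when a nucleotide string violates the CDS invariants."""


def translate_cds(nt: str) -> str:
    """Translate an in-frame CDS under the standard genetic code.

    Raises :class:`InvalidCDSError` on internal stop codons, ambiguous
    bases or lengths that are not a multiple of 3.  Terminal stops are the
    caller's concern; this function treats any stop as internal.
    """
    if len(nt) % 3:
        raise InvalidCDSError(f"length {len(nt)} is not a multiple of 3")
    if not set(nt) <= _VALID_NT:
        bad = sorted(set(nt) - _VALID_NT)
        raise InvalidCDSError(f"ambiguous/invalid bases {bad}")
    for i in range(0, len(nt), 3):
        if nt[i : i + 3] in STOP_CODONS:
            raise InvalidCDSError(f"stop codon {nt[i:i + 3]} at nt position {i}")
    return str(Seq(nt).translate())


@dataclass(frozen=True)
class CodingSequence:
    """One gene: an in-frame nucleotide CDS and its derived peptide."""

    id: str
    nt: str
    pep: str = field(compare=False)

    @classmethod
    def from_nt(cls, id: str, nt: str) -> "CodingSequence":
        """Validate and build a record; strips one terminal stop codon."""
        nt = nt.upper()
        if len(nt) < 9:
            raise InvalidCDSError(f"{id}: CDS shorter than 9 nt")
        if len(nt) % 3 == 0 and nt[-3:] in STOP_CODONS:
            nt = nt[:-3]
        return cls(id=id, nt=nt, pep=translate_cds(nt))

    def __len__(self) -> int:
        return len(self.nt)


def read_cds_fasta(path: str | Path) -> list[CodingSequence]:
    """Read a nucleotide CDS FASTA, validating every record.

    Records failing the CDS invariants are skipped with a logged warning;
    duplicate ids and an empty valid set are fatal.
    """
    path = Path(path)
    records: list[CodingSequence] = []
    seen: set[str] = set()
    skipped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        try:
            records.append(CodingSequence.from_nt(rec.id, str(rec.seq)))
        except InvalidCDSError as exc:
            skipped += 1
            logger.warning("skipping %s: %s", rec.id, exc)
    if skipped:
        logger.warning("%s: skipped %d invalid CDS record(s)", path, skipped)
    if not records:
        raise ValueError(f"no valid CDS records in {path}")
    return records


def write_cds_fasta(records: Iterable[CodingSequence], path: str | Path,
                    peptide: bool = False) -> None:
    """Write records as FASTA (nucleotide CDS, or peptides if requested)."""
    seqs = [
        SeqRecord(Seq(r.pep if peptide else r.nt), id=r.id, description="")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def _fmt(value) -> str:
    if isinstance(value, float):
        if math.isinf(value):
            return "inf"
        if math.isnan(value):
            return "nan"
        return f"{value:.6g}"
    return str(value)


def write_tsv(records: Sequence[Mapping], path: str | Path,
              columns: Sequence[str] | None = None) -> None:
    """Write rows as a TSV with a header, floats at 6 significant digits.

    Rows are sorted by their first column so re-runs are byte-identical.
    An empty record list yields a header-only file (columns must then be
    given) and a warning.
    """
    if not records:
        logger.warning("write_tsv: no records, writing header only to %s", path)
        if columns is None:
            raise ValueError("columns required when records are empty")
    if columns is None:
        columns = list(records[0].keys())
    lines = ["\t".join(columns)]
    body = sorted(
        ("\t".join(_fmt(row[c]) for c in columns) for row in records),
    )
    lines.extend(body)
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class PipelineConfig:
    """Thresholds and knobs for the whole analysis.

    Defaults follow the standard paranome-construction recipe: similarity
    graph edges at E <= 1e-10, subfamily splitting at Ks <= 5, orthologs
    at >= 30% identity over >= 150 aligned amino acids, MCL inflation 2.0,
    BLOSUM62 with affine gaps 11/1.
    """

    evalue_cutoff: float = 1e-10
    ks_max: float = 5.0
    rbh_min_identity: float = 30.0
    rbh_min_aln_len: int = 150
    mcl_inflation: float = 2.0
    gap_open: int = 11
    gap_extend: int = 1
    kde_bandwidth: float | str = "auto"
    min_ks: float = 0.05
    rng_seed: int = 42

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")
        if self.ks_max <= 0:
            raise ValueError("ks_max must be > 0")
        if not 0 < self.rbh_min_identity <= 100:
            raise ValueError("rbh_min_identity must be in (0, 100]")
        if self.rbh_min_aln_len < 1:
            raise ValueError("rbh_min_aln_len must be >= 1")
        if self.mcl_inflation <= 1:
            raise ValueError("mcl_inflation must be > 1")
        if isinstance(self.kde_bandwidth, (int, float)) and self.kde_bandwidth <= 0:
            raise ValueError("kde_bandwidth must be > 0 or 'auto'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        section = data.get("pipeline", data)
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in section.items() if k in known})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({"pipeline": self.__dict__}))


def setup_logging(logfile: str | Path | None = None,
                  level: int = logging.INFO) -> None:
    """Route pipeline logging to stderr and optionally a plain-text file."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(str(logfile)))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    logger.setLevel(level)
    logger.handlers.clear()
    for h in handlers:
        h.setFormatter(fmt)
        logger.addHandler(h)
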