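"""Reference-guided multiple sequence alignment container and FASTA I/O.

The MSA holds equal-length gapped rows over ``{A,C,G,T,N,-}``: the linear
reference plus one row per founder sequence. It is *reference-guided*: it
only needs to be consistent with each founder's pairwise alignment to the
reference, not optimal, which is all the coordinate projection requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"
ALPHABET = frozenset("ACGTN-")

FASTA_WIDTH = 80


@dataclass
class GappedSequence:
    symbols: str

    def __post_init__(self):
        if not self.symbols:
            raise ValueError("gapped sequence must be non-empty")
        bad = set(self.symbols.upper()) - ALPHABET
        if bad:
            raise ValueError(f"illegal symbols in gapped sequence: {sorted(bad)}")
        self.symbols = self.symbols.upper()

    def ungapped(self) -> str:
        return self.symbols.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class ReferenceGuidedMSA:
    """Equal-length gapped rows (reference + founders), reference named."""

    reference_name: str
    rows: dict = field(default_factory=dict)  # name -> str (gapped), ordered

    def __post_init__(self):
        self.rows = {name: (row.symbols if isinstance(row, GappedSequence) else str(row).upper())
                     for name, row in self.rows.items()}
        self.validate()

    def validate(self) -> None:
        if self.reference_name not in self.rows:
            raise ValueError(f"reference row {self.reference_name!r} missing from MSA")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"MSA rows have unequal lengths: {sorted(lengths)}")
        for name, row in self.rows.items():
            bad = set(row) - ALPHABET
            if bad:
                raise ValueError(f"illegal symbols in MSA row {name!r}: {sorted(bad)}")
        if set(self.rows[self.reference_name]) == {GAP}:
            raise ValueError("reference row is all gaps")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def ungapped(self, name: str) -> str:
        return self.rows[name].replace(GAP, "")

    def founder_names(self):
        return [n for n in self.rows if n != self.reference_name]


def write_aligned_fasta(msa: ReferenceGuidedMSA, path) -> None:
    records = [SeqRecord(Seq(row), id=name, description="") for name, row in msa.rows.items()]
    _write_fasta(records, path)


def read_aligned_fasta(path, reference_name: str) -> ReferenceGuidedMSA:
    rows = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not rows:
        raise ValueError(f"no FASTA records in {path}")
    return ReferenceGuidedMSA(reference_name=reference_name, rows=rows)


def _write_fasta(records, path) -> None:
    try:
        with open(path, "w") as handle:
            writer = SeqIO.FastaIO.FastaWriter(handle, wrap=FASTA_WIDTH)
            writer.write_file(records)
    except OSError as exc:
        raise OSError(f"failed writing FASTA to {path}: {exc}") from exc


def write_fasta_sequences(named_seqs, path) -> None:
    """Write ``(name, ungapped sequence)`` pairs as FASTA (80-column lines)."""
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in named_seqs]
    _write_fasta(records, path)


def read_fasta_sequences(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
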