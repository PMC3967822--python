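"""Genome reading, window fragmentation, N filtering, and subsampling.

Genomes are cut into fixed-size windows under three standard regimes:
non-overlapping 5 kb, non-overlapping 10 kb, and overlapping 100 kb windows
with a 10 kb sliding step.  Windows whose undetermined-base (N) fraction
exceeds 10% of the window size are omitted; the rest carry an *effective
length* (window minus Ns) used downstream to normalize oligonucleotide
frequencies.  Large genomes can be randomly subsampled to a per-genome base
cap (200 Mb in the original large-genome setting) so small genomes are not
swamped on the map.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "IngestError",
    "RANKS",
    "GenomeRecord",
    "FragmentationScheme",
    "Fragment",
    "read_taxon_table",
    "read_genomes",
    "fragment_genome",
    "subsample_fragments",
    "write_fragments_tsv",
    "write_fragments_fasta",
    "read_fragments",
]

RANKS = ("species", "genus", "family", "group")

# case-fold and collapse every non-ACGT character (IUPAC ambiguity codes
# included) to N; N is the conservative superset for the 10% rule
_CANONICALIZE = str.maketrans(
    {i: (chr(i).upper() if chr(i).upper() in "ACGT" else "N") for i in range(256)}
)


class IngestError(ValueError):
    """Raised for malformed inputs: missing labels, empty files, bad schemes."""


def canonicalize_sequence(seq: str) -> str:
    return seq.translate(_CANONICALIZE)


@dataclass
class GenomeRecord:
    """One genome: id, taxon labels by rank, and its canonicalized sequence.

    Multi-contig genomes are concatenated in file order; ``contig_bounds``
    keeps the original boundaries so windows never span two contigs.
    """

    genome_id: str
    taxon: dict[str, str]
    sequence: str
    contig_bounds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if not self.contig_bounds:
            self.contig_bounds = ((0, len(self.sequence)),)


@dataclass(frozen=True)
class FragmentationScheme:
    """Windowing parameters: window/step sizes, N-fraction filter, subsample cap."""

    window_length: int
    step: int | None = None
    n_fraction_threshold: float = 0.10
    subsample_cap: int | None = None
    rng_seed: int = 0

    def __post_init__(self):
        step = self.window_length if self.step is None else self.step
        object.__setattr__(self, "step", step)
        if self.window_length <= 0:
            raise IngestError(f"window_length must be positive, got {self.window_length}")
        if not 0 < step <= self.window_length:
            raise IngestError(
                f"step must satisfy 0 < step <= window_length, got {step}"
            )
        if not 0 <= self.n_fraction_threshold < 1:
            raise IngestError(
                f"n_fraction_threshold must be in [0, 1), got {self.n_fraction_threshold}"
            )
        if self.subsample_cap is not None and self.subsample_cap <= 0:
            raise IngestError(f"subsample_cap must be positive, got {self.subsample_cap}")


@dataclass
class Fragment:
    """One genomic window: 0-based half-open coordinates on the registered strand."""

    genome_id: str
    start: int
    end: int
    sequence: str
    n_count: int

    @property
    def effective_length(self) -> int:
        """Window length minus undetermined bases — the 'length without Ns'."""
        return self.end - self.start - self.n_count


def read_taxon_table(table) -> pd.DataFrame:
    """Load the genome_id -> rank-label table (TSV with header) as a DataFrame."""
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)
    if "genome_id" not in df.columns:
        raise IngestError("taxon table must have a 'genome_id' column")
    for rank in RANKS:
        if rank not in df.columns:
            df[rank] = ""
    if df["genome_id"].duplicated().any():
        dup = df.loc[df["genome_id"].duplicated(), "genome_id"].iloc[0]
        raise IngestError(f"duplicate genome_id {dup!r} in taxon table")
    return df.set_index("genome_id", drop=False)


def _open_fasta(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_genomes(fasta_paths: Sequence, taxon_table) -> list[GenomeRecord]:
    """Read multi-FASTA files into GenomeRecords with taxon labels attached.

    Sequences are uppercased and all non-ACGT IUPAC codes become N.  Records
    sharing an id are treated as contigs of one genome and concatenated in
    file order (contig boundaries retained).  Every record id must appear in
    the taxon table.
    """
    taxa = read_taxon_table(taxon_table)
    pieces: dict[str, list[str]] = {}
    order: list[str] = []
    for path in fasta_paths:
        path = Path(path)
        count = 0
        with _open_fasta(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                count += 1
                if rec.id not in taxa.index:
                    raise IngestError(
                        f"record {rec.id!r} (file {path.name}) is missing from the taxon table"
                    )
                if rec.id not in pieces:
                    pieces[rec.id] = []
                    order.append(rec.id)
                pieces[rec.id].append(canonicalize_sequence(str(rec.seq)))
        if count == 0:
            raise IngestError(f"FASTA file {path} contains no records")
    records = []
    for gid in order:
        contigs = pieces[gid]
        bounds, pos = [], 0
        for c in contigs:
            bounds.append((pos, pos + len(c)))
            pos += len(c)
        row = taxa.loc[gid]
        taxon = {rank: str(row[rank]) for rank in RANKS}
        records.append(GenomeRecord(gid, taxon, "".join(contigs), tuple(bounds)))
    return records


def fragment_genome(
    genome: GenomeRecord, scheme: FragmentationScheme
) -> list[Fragment]:
    """Tile a genome into windows, dropping trailing partials and N-heavy windows.

    Windows start at 0, step, 2*step, ... within each contig; a window whose N
    fraction exceeds the threshold is omitted, the rest carry
    effective_length = window - n_count.
    """
    w, step, thr = scheme.window_length, scheme.step, scheme.n_fraction_threshold
    fragments: list[Fragment] = []
    for cstart, cend in genome.contig_bounds:
        for s in range(cstart, cend - w + 1, step):
            window = genome.sequence[s : s + w]
            n = window.count("N")
            if n / w > thr:
                continue
            fragments.append(Fragment(genome.genome_id, s, s + w, window, n))
    return fragments


def subsample_fragments(
    fragments: Sequence[Fragment], cap: int, rng_seed: int = 0
) -> list[Fragment]:
    """Seeded uniform subsample keeping total window bases <= cap.

    Identity when already under the cap; otherwise keeps a uniform random
    subset (without replacement) of floor(cap / window_length) fragments,
    preserving input order.  Pure function of (fragment order, cap, seed).
    """
    if cap <= 0:
        raise IngestError(f"cap must be positive, got {cap}")
    fragments = list(fragments)
    total = sum(f.end - f.start for f in fragments)
    if total <= cap:
        return fragments
    window = fragments[0].end - fragments[0].start
    n_keep = cap // window
    rng = np.random.default_rng(rng_seed)
    idx = np.sort(rng.choice(len(fragments), size=n_keep, replace=False))
    return [fragments[i] for i in idx]


_TSV_HEADER = "# fragment coordinates are 0-based half-open on the registered strand\n"


def write_fragments_tsv(fragments: Iterable[Fragment], path) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER)
        fh.write("genome_id\tstart\tend\tn_count\n")
        for f in fragments:
            fh.write(f"{f.genome_id}\t{f.start}\t{f.end}\t{f.n_count}\n")


def write_fragments_fasta(fragments: Iterable[Fragment], path) -> None:
    """Fragment sequences as FASTA with ids genome_id:start-end."""
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f">{f.genome_id}:{f.start}-{f.end}\n")
            seq = f.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_fragments(tsv_path, fasta_path) -> list[Fragment]:
    """Round-trip loader for the TSV + FASTA pair written by the writers above."""
    seqs: dict[tuple[str, int], str] = {}
    with open(fasta_path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            gid, span = rec.id.rsplit(":", 1)
            start = int(span.split("-")[0])
            seqs[(gid, start)] = str(rec.seq)
    frags = []
    df = pd.read_csv(tsv_path, sep="\t", comment="#", dtype={"genome_id": str})
    for row in df.itertuples(index=False):
        seq = seqs[(row.genome_id, int(row.start))]
        frags.append(
            Fragment(row.genome_id, int(row.start), int(row.end), seq, int(row.n_count))
        )
    return frags
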