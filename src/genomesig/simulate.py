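"""Synthetic genomes with controlled signature structure.

Real genome signatures arise from lineage-specific mutation/repair biases
that shape short-oligonucleotide usage (CpG depletion being the textbook
case).  This module emulates them with order-m Markov chains over ACGT:
each species gets a base composition (GC content), an optional set of
dinucleotide transition biases, and optional motif enrichments/depletions
injected by rejection-resampling until the genome-wide observed/expected
ratio of the motif's complementary pair-set reaches the requested
fold-change.  Everything is seeded and byte-reproducible, so every pipeline
stage has ground truth without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from numba import njit

from .ingest import RANKS, GenomeRecord
from .kmers import BASES, encode, reverse_complement, window_codes

__all__ = [
    "SimulationError",
    "SpeciesModel",
    "uniform_chain",
    "dinucleotide_chain",
    "calibrated_chain",
    "stationary_composition",
    "generate_genome",
    "generate_records",
    "generate_study",
    "load_scenario",
    "default_study",
    "depletion_study",
    "gc_gradient_study",
]

_BASE_BYTES = np.frombuffer(b"ACGTN", dtype=np.uint8)


class SimulationError(ValueError):
    """Raised for invalid models or unattainable motif adjustments."""


@dataclass
class SpeciesModel:
    """Order-m Markov genome model with optional motif fold-changes.

    transitions has shape (4**order, 4): conditional base probabilities given
    the previous ``order`` bases (contexts in lexicographic base-4 order).
    motif_adjustments is a sequence of (word, fold) pairs; fold < 1 depletes,
    fold > 1 enriches the word's complementary pair-set relative to the
    unadjusted chain.  n_runs is a sequence of (position, length) N blocks
    written over the finished sequence.
    """

    species_id: str
    transitions: np.ndarray
    group_id: str = ""
    family_id: str = ""
    genus_id: str = ""
    order: int = 0
    motif_adjustments: tuple[tuple[str, float], ...] = ()
    genome_length: int = 600_000
    n_runs: tuple[tuple[int, int], ...] = ()
    rng_seed: int = 0

    def __post_init__(self):
        self.transitions = np.asarray(self.transitions, dtype=np.float64)
        if not 0 <= self.order <= 3:
            raise SimulationError(f"order must be in [0, 3], got {self.order}")
        if self.transitions.shape != (4**self.order, 4):
            raise SimulationError(
                f"transitions shape {self.transitions.shape} does not match "
                f"order {self.order} (expected {(4**self.order, 4)})"
            )
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-9):
            raise SimulationError("transition rows must each sum to 1")
        if (self.transitions < 0).any():
            raise SimulationError("transition probabilities must be non-negative")
        for word, fold in self.motif_adjustments:
            if fold <= 0:
                raise SimulationError(f"fold-change for {word!r} must be > 0")

    @property
    def taxon(self) -> dict[str, str]:
        return {
            "species": self.species_id,
            "genus": self.genus_id,
            "family": self.family_id,
            "group": self.group_id,
        }


def uniform_chain(gc: float) -> np.ndarray:
    """Order-0 model with the given G+C fraction (strand-symmetric)."""
    if not 0 < gc < 1:
        raise SimulationError(f"gc must be in (0, 1), got {gc}")
    return np.array([[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]])


def dinucleotide_chain(gc: float, factors: dict[str, float] | None = None) -> np.ndarray:
    """Order-1 model: independent chain at ``gc`` with dinucleotide biases.

    factors maps dinucleotides ("CG": 0.3 means P(G | previous C) scaled by
    0.3 before row renormalization) — the standard way to emulate CpG-like
    depletion or enrichment.
    """
    base = uniform_chain(gc)[0]
    trans = np.tile(base, (4, 1))
    for dinuc, f in (factors or {}).items():
        if len(dinuc) != 2 or any(b not in BASES for b in dinuc.upper()):
            raise SimulationError(f"invalid dinucleotide {dinuc!r}")
        if f <= 0:
            raise SimulationError(f"factor for {dinuc!r} must be > 0")
        i, j = BASES.index(dinuc[0].upper()), BASES.index(dinuc[1].upper())
        trans[i, j] *= f
    return trans / trans.sum(axis=1, keepdims=True)


def stationary_composition(transitions: np.ndarray) -> np.ndarray:
    """Stationary base frequencies of an order-1 chain (left eigenvector at 1)."""
    P = np.asarray(transitions, dtype=np.float64)
    if P.shape == (1, 4):
        return P[0]
    evals, evecs = np.linalg.eig(P.T)
    v = np.real(evecs[:, np.argmin(np.abs(evals - 1.0))])
    v = np.abs(v)
    return v / v.sum()


def calibrated_chain(gc: float, factors: dict[str, float] | None = None) -> np.ndarray:
    """Order-1 chain with dinucleotide biases whose *stationary* GC equals gc.

    Transition biases shift the stationary composition away from the base
    probabilities they were built from; this bisects the base GC until the
    stationary GC matches the target, so a model's nominal GC means what it
    says regardless of its dinucleotide structure.
    """
    if not 0 < gc < 1:
        raise SimulationError(f"gc must be in (0, 1), got {gc}")

    def achieved(x: float) -> float:
        comp = stationary_composition(dinucleotide_chain(x, factors))
        return float(comp[1] + comp[2])

    lo, hi = 1e-3, 1 - 1e-3
    for _ in range(60):
        mid = (lo + hi) / 2
        if achieved(mid) < gc:
            lo = mid
        else:
            hi = mid
    return dinucleotide_chain((lo + hi) / 2, factors)


@njit(cache=False)
def _sample_chain(cdf, ctx_mask, n, u, out):  # pragma: no cover - numba kernel
    ctx = 0
    for t in range(n):
        row = cdf[ctx]
        r = u[t]
        b = 0
        while b < 3 and row[b] < r:
            b += 1
        out[t] = b
        ctx = ((ctx << 2) | b) & ctx_mask


def _sample_codes(model: SpeciesModel, rng: np.random.Generator, n: int) -> np.ndarray:
    burn = 64 if model.order > 0 else 0
    cdf = np.cumsum(model.transitions, axis=1)
    cdf[:, -1] = 1.0
    u = rng.random(n + burn)
    out = np.empty(n + burn, dtype=np.int8)
    _sample_chain(cdf, 4**model.order - 1, n + burn, u, out)
    return out[burn:]


def _set_occurrences(codes: np.ndarray, word: str) -> np.ndarray:
    """Start positions of a word or its reverse complement on the sequence."""
    k = len(word)
    wcodes, ok = window_codes(codes.astype(np.uint8), k)
    targets = {_word_code(word)}
    targets.add(_word_code(reverse_complement(word)))
    hit = np.zeros(len(wcodes), dtype=bool)
    for t in targets:
        hit |= wcodes == t
    return np.flatnonzero(hit & ok)


def _word_code(word: str) -> int:
    code = 0
    for b in word.upper():
        code = (code << 2) | BASES.index(b)
    return code


def _adjust_motifs(
    codes: np.ndarray,
    model: SpeciesModel,
    rng: np.random.Generator,
    max_rounds: int = 80,
    rel_tol: float = 0.10,
) -> np.ndarray:
    """Rejection-resample local windows until each motif's pair-set count is
    within ``rel_tol`` of fold * baseline."""
    cdf = np.cumsum(model.transitions, axis=1)
    cdf[:, -1] = 1.0
    mask = 4**model.order - 1
    targets = []
    for word, fold in model.motif_adjustments:
        baseline = len(_set_occurrences(codes, word))
        targets.append((word.upper(), fold, baseline, fold * baseline))

    def redraw(pos: int, k: int) -> None:
        ctx = 0
        for p in range(max(0, pos - model.order), pos):
            ctx = ((ctx << 2) | int(codes[p])) & mask
        for p in range(pos, pos + k):
            r = rng.random()
            row = cdf[ctx]
            b = 0
            while b < 3 and row[b] < r:
                b += 1
            codes[p] = b
            ctx = ((ctx << 2) | b) & mask

    for _ in range(max_rounds):
        done = True
        for word, fold, baseline, target in targets:
            k = len(word)
            occ = _set_occurrences(codes, word)
            cur = len(occ)
            slack = max(rel_tol * target, 1.0)
            if abs(cur - target) <= slack:
                continue
            done = False
            if cur > target:
                excess = int(round(cur - target))
                for pos in rng.choice(occ, size=min(excess, len(occ)), replace=False):
                    redraw(int(pos), k)
            else:
                deficit = int(round(target - cur))
                wcode = _word_code(word)
                rcode = _word_code(reverse_complement(word))
                positions = rng.integers(0, len(codes) - k, size=deficit)
                for pos in positions:
                    chosen = wcode if rng.random() < 0.5 else rcode
                    for jj in range(k - 1, -1, -1):
                        codes[pos + jj] = chosen & 3
                        chosen >>= 2
        if done:
            return codes
    achieved = {
        word: (len(_set_occurrences(codes, word)) / baseline if baseline else np.nan)
        for word, fold, baseline, _ in targets
    }
    raise SimulationError(
        f"motif adjustment did not converge after {max_rounds} rounds; "
        f"achieved ratios {achieved}"
    )


def generate_genome(model: SpeciesModel) -> GenomeRecord:
    """Sample one genome from the model (seeded, reproducible)."""
    rng = np.random.default_rng(model.rng_seed)
    codes = _sample_codes(model, rng, model.genome_length)
    if model.motif_adjustments:
        codes = _adjust_motifs(codes, model, rng)
    codes = codes.astype(np.uint8)
    for pos, length in model.n_runs:
        if not 0 <= pos <= len(codes) - length:
            raise SimulationError(f"N run at {pos} (+{length}) exceeds the genome")
        codes[pos : pos + length] = 4
    sequence = _BASE_BYTES[codes].tobytes().decode()
    return GenomeRecord(model.species_id, model.taxon, sequence)


def generate_records(models) -> list[GenomeRecord]:
    ids = [m.species_id for m in models]
    if len(set(ids)) != len(ids):
        raise SimulationError("duplicate species_ids in study")
    return [generate_genome(m) for m in models]


def generate_study(models, outdir) -> tuple[list[Path], Path]:
    """Write one FASTA per species plus the taxon TSV; fully seeded.

    Returns (fasta paths, taxon table path); output is byte-identical for
    identical model seeds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = generate_records(models)
    paths = []
    for rec in records:
        path = outdir / f"{rec.genome_id}.fasta"
        with open(path, "w") as fh:
            fh.write(f">{rec.genome_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
        paths.append(path)
    table = outdir / "taxa.tsv"
    with open(table, "w") as fh:
        fh.write("genome_id\t" + "\t".join(RANKS) + "\n")
        for rec in records:
            fh.write(
                rec.genome_id + "\t" + "\t".join(rec.taxon[r] for r in RANKS) + "\n"
            )
    return paths, table


def load_scenario(path) -> list[SpeciesModel]:
    """Build SpeciesModels from a YAML scenario file.

    Each entry under ``species`` takes: species_id, group, family, genus, gc,
    dinucleotide_factors, motifs ({word: fold}), genome_length, seed.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    base_seed = int(doc.get("seed", 0))
    models = []
    for i, sp in enumerate(doc["species"]):
        factors = sp.get("dinucleotide_factors")
        if factors:
            trans, order = dinucleotide_chain(float(sp["gc"]), factors), 1
        else:
            trans, order = uniform_chain(float(sp["gc"])), 0
        motifs = tuple((w, float(f)) for w, f in (sp.get("motifs") or {}).items())
        models.append(
            SpeciesModel(
                species_id=str(sp["species_id"]),
                group_id=str(sp.get("group", "")),
                family_id=str(sp.get("family", "")),
                genus_id=str(sp.get("genus", "")),
                order=order,
                transitions=trans,
                motif_adjustments=motifs,
                genome_length=int(sp.get("genome_length", 600_000)),
                n_runs=tuple(tuple(x) for x in sp.get("n_runs", ())),
                rng_seed=int(sp.get("seed", base_seed * 100_003 + i) % 2**31),
            )
        )
    return models


# ------------------------------------------------------------ study presets

# Five groups of closely related species (sizes 3+3+2+2+2 = 12), emulating
# congeneric insect genomes: stationary GC steps of 0.008 and modest
# CpG/TpA contrasts.  Adjacent groups are ~5-10 sigma apart at 100 kb but
# only ~2 sigma apart at 5 kb, so clustering degrades as windows shrink.
_GROUP_SPECS = (
    ("groupA", 0.418, {"CG": 0.50, "TA": 1.24}, 3),
    ("groupB", 0.430, {"CG": 0.64, "TA": 1.12}, 3),
    ("groupC", 0.442, {"CG": 0.78, "TA": 1.00}, 2),
    ("groupD", 0.454, {"CG": 0.92, "TA": 0.88}, 2),
    ("groupE", 0.466, {"CG": 1.06, "TA": 0.76}, 2),
)


def default_study(
    seed: int = 0,
    genome_length: int = 600_000,
    extra_motifs: dict[str, tuple[tuple[str, float], ...]] | None = None,
) -> list[SpeciesModel]:
    """The package's standard 5-group / 12-species synthetic study.

    extra_motifs optionally maps a group id to motif adjustments applied to
    every species of that group.
    """
    models = []
    idx = 0
    for g, (gid, gc, factors, n_species) in enumerate(_GROUP_SPECS):
        for s in range(n_species):
            jitter = {"CG": factors["CG"] * (1.0 + 0.04 * s), "TA": factors["TA"]}
            models.append(
                SpeciesModel(
                    species_id=f"{gid}_sp{s + 1}",
                    group_id=gid,
                    family_id="familyI" if g < 3 else "familyII",
                    genus_id=gid,
                    order=1,
                    transitions=calibrated_chain(gc + 0.003 * (s - 1), jitter),
                    motif_adjustments=(extra_motifs or {}).get(gid, ()),
                    genome_length=genome_length,
                    rng_seed=(seed * 100_003 + 7 * idx + 1) % 2**31,
                )
            )
            idx += 1
    return models


def depletion_study(
    seed: int = 0, word: str = "CTTCG", fold: float = 0.2, group: str = "groupA",
    genome_length: int = 600_000,
) -> list[SpeciesModel]:
    """Default study with one motif pair-set depleted in a single group —
    the synthetic analog of a group-diagnostic underrepresented word."""
    return default_study(
        seed, genome_length=genome_length, extra_motifs={group: ((word, fold),)}
    )


def gc_gradient_study(
    seed: int = 0, n_species: int = 6, gc_range: tuple[float, float] = (0.35, 0.55),
    genome_length: int = 400_000,
) -> list[SpeciesModel]:
    """Order-0 species differing only in GC, spanning gc_range evenly."""
    lo, hi = gc_range
    models = []
    for s in range(n_species):
        gc = lo + (hi - lo) * s / (n_species - 1)
        models.append(
            SpeciesModel(
                species_id=f"gc{int(round(gc * 1000)):03d}",
                group_id=f"g{s + 1}",
                family_id=f"g{s + 1}",
                order=0,
                transitions=uniform_chain(gc),
                genome_length=genome_length,
                rng_seed=(seed * 100_003 + 13 * s + 3) % 2**31,
            )
        )
    return models
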