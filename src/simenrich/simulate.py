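"""Seeded synthetic data: proteomes with planted SIMs, enriched hit lists,
and two-group LFQ matrices with planted effects.

Every generator is a pure function of its model and seed, and returns
the ground truth needed to score recovery without re-deriving it.

Planted SIMs are written over existing residues (not inserted), so
sequence lengths stay exactly as drawn and STAA denominators remain
controlled.  When L/I/V are present in the background alphabet,
incidental matches arise on top of the planted ones; recovery tests
that need exact control can use the L/I/V-free background alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ProteinList, ProteinRecord, Proteome
from .lfq import LFQ_PREFIX, LFQTable
from .scan import PatternClass

__all__ = [
    "ProteomeModel",
    "HitListModel",
    "LFQModel",
    "HUMAN_AA_FREQS",
    "generate_proteome",
    "generate_hit_list",
    "generate_lfq",
]

# Approximate residue frequencies of the reviewed human proteome.
HUMAN_AA_FREQS: dict[str, float] = {
    "A": 0.0702, "R": 0.0564, "N": 0.0359, "D": 0.0473, "C": 0.0230,
    "Q": 0.0477, "E": 0.0710, "G": 0.0657, "H": 0.0263, "I": 0.0433,
    "L": 0.0996, "K": 0.0572, "M": 0.0213, "F": 0.0365, "P": 0.0631,
    "S": 0.0833, "T": 0.0536, "W": 0.0122, "Y": 0.0266, "V": 0.0598,
}

PSI_CHOICES = np.array(list("LIV"))


def _resolve_freqs(alphabet: str,
                   custom: Mapping[str, float] | None) -> tuple[np.ndarray, np.ndarray]:
    if custom is not None:
        table = dict(custom)
    elif alphabet == "human":
        table = dict(HUMAN_AA_FREQS)
    elif alphabet == "uniform":
        table = {aa: 1.0 for aa in HUMAN_AA_FREQS}
    elif alphabet == "liv_free":
        table = {aa: f for aa, f in HUMAN_AA_FREQS.items() if aa not in "LIV"}
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    letters = np.array(list(table.keys()))
    freqs = np.array(list(table.values()), dtype=float)
    if (freqs < 0).any() or freqs.sum() <= 0:
        raise ValueError("invalid frequency table")
    return letters, freqs / freqs.sum()


@dataclass(frozen=True)
class ProteomeModel:
    """Synthetic proteome: i.i.d. residues + planted SIM motifs.

    Lengths are log-normal with the given median and log-scale sigma
    (human-like defaults: median 375 aa, sigma 0.65).  ``sim_rate`` is
    the planting rate in motifs per 1000 residues, on top of whatever
    incidental matches the background composition produces.
    """

    n_proteins: int = 1000
    length_median: float = 375.0
    length_sigma: float = 0.65
    min_length: int = 30
    alphabet: str = "human"  # "human" | "uniform" | "liv_free"
    aa_freqs: Mapping[str, float] | None = None
    sim_rate: float = 0.0  # planted motifs per 1000 aa
    seed: int = 0
    accession_prefix: str = "SYN"

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.sim_rate < 0:
            raise ValueError("sim_rate must be >= 0")
        _resolve_freqs(self.alphabet, self.aa_freqs)


@dataclass(frozen=True)
class HitListModel:
    """A hit list of k proteins planted at ``enrichment_factor`` times the
    background SIM rate."""

    k: int = 59
    enrichment_factor: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.enrichment_factor <= 0:
            raise ValueError("enrichment_factor must be > 0")


@dataclass(frozen=True)
class LFQModel:
    """Two-group x n-replicate LFQ matrix with planted log2 effects.

    Base log2 intensities are normal (i.e. linear intensities are
    log-normal); the planted effect is added to group A for the first
    ``n_hits`` proteins.  Dropout probability falls logistically with
    log2 intensity (midpoint/scale), emulating low-abundance
    missingness.  Peptide counts are 1 + Poisson(mean − 1).
    """

    n_proteins: int = 500
    n_hits: int = 50
    effect: float = 2.0
    noise_sd: float = 0.5
    n_replicates: int = 3
    base_mean: float = 26.0
    base_sd: float = 2.0
    dropout_midpoint: float = 22.0
    dropout_scale: float = 1.0
    dropout_max: float = 0.9
    peptide_mean: float = 6.0
    seed: int = 0
    group_a: str = "WT"
    group_b: str = "control"

    def __post_init__(self) -> None:
        if not 0 <= self.n_hits <= self.n_proteins:
            raise ValueError("need 0 <= n_hits <= n_proteins")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per group")


def _plant_motifs(seq: np.ndarray, n_motifs: int,
                  rng: np.random.Generator) -> list[tuple[int, int, PatternClass]]:
    """Overwrite residues with n non-overlapping SIM motifs; returns plants."""
    length = seq.size
    if n_motifs == 0:
        return []
    if 4 * n_motifs > length:
        raise ValueError(
            f"cannot fit {n_motifs} motifs without overlap in {length} residues"
        )
    patterns = [list(PatternClass)[i] for i in rng.integers(0, 3, size=n_motifs)]
    planted: list[tuple[int, int, PatternClass]] = []
    occupied = np.zeros(length, dtype=bool)
    for pattern in patterns:
        plen = pattern.length
        placed = False
        for _ in range(1000):
            start = int(rng.integers(0, length - plen + 1))
            if not occupied[start: start + plen].any():
                placed = True
                break
        if not placed:
            raise ValueError("planting density infeasible (no free window found)")
        occupied[start: start + plen] = True
        window = seq[start: start + plen].copy()
        for off in range(plen):
            if off in pattern.psi_offsets:
                window[off] = PSI_CHOICES[rng.integers(0, 3)]
        seq[start: start + plen] = window
        planted.append((start, start + plen, pattern))
    planted.sort()
    return planted


def generate_proteome(
    model: ProteomeModel,
) -> tuple[Proteome, dict[str, list[tuple[int, int, PatternClass]]]]:
    """Generate a synthetic proteome; returns (proteome, planted ground truth).

    Ground truth maps accession -> list of (start, end, pattern) for
    every planted motif.
    """
    rng = np.random.default_rng(model.seed)
    letters, freqs = _resolve_freqs(model.alphabet, model.aa_freqs)
    mu = np.log(model.length_median)
    lengths = np.maximum(
        np.rint(np.exp(rng.normal(mu, model.length_sigma,
                                  size=model.n_proteins))).astype(int),
        model.min_length,
    )
    width = len(str(model.n_proteins))
    records = []
    truth: dict[str, list[tuple[int, int, PatternClass]]] = {}
    for i, length in enumerate(lengths):
        seq = letters[rng.choice(letters.size, size=length, p=freqs)]
        n_plant = int(rng.poisson(model.sim_rate * length / 1000.0))
        planted = _plant_motifs(seq, n_plant, rng)
        acc = f"{model.accession_prefix}{i + 1:0{width}d}"
        records.append(ProteinRecord(accession=acc, sequence="".join(seq)))
        truth[acc] = planted
    return Proteome(records, source_label=f"synthetic(seed={model.seed})"), truth


def generate_hit_list(
    background: ProteomeModel, hits: HitListModel,
) -> tuple[Proteome, ProteinList, dict[str, list[tuple[int, int, PatternClass]]]]:
    """Generate one proteome in which k 'hit' proteins carry SIMs at
    ``enrichment_factor`` times the background planting rate.

    Returns (merged proteome, hit list, planted ground truth).  The hit
    proteins are the first k records; the remaining
    ``background.n_proteins − k`` form the background frame.
    """
    if hits.k > background.n_proteins:
        raise ValueError("hit-list size exceeds the proteome size")
    rng = np.random.default_rng(hits.seed)
    letters, freqs = _resolve_freqs(background.alphabet, background.aa_freqs)
    mu = np.log(background.length_median)
    lengths = np.maximum(
        np.rint(np.exp(rng.normal(mu, background.length_sigma,
                                  size=background.n_proteins))).astype(int),
        background.min_length,
    )
    hit_rate = hits.enrichment_factor * background.sim_rate
    width = len(str(background.n_proteins))
    records = []
    truth: dict[str, list[tuple[int, int, PatternClass]]] = {}
    members = []
    for i, length in enumerate(lengths):
        is_hit = i < hits.k
        rate = hit_rate if is_hit else background.sim_rate
        seq = letters[rng.choice(letters.size, size=length, p=freqs)]
        n_plant = int(rng.poisson(rate * length / 1000.0))
        planted = _plant_motifs(seq, n_plant, rng)
        prefix = "HIT" if is_hit else background.accession_prefix
        acc = f"{prefix}{i + 1:0{width}d}"
        records.append(ProteinRecord(accession=acc, sequence="".join(seq)))
        truth[acc] = planted
        if is_hit:
            members.append(acc)
    proteome = Proteome(records, source_label=f"synthetic(seed={hits.seed})")
    return proteome, ProteinList(label="planted_hits", members=members), truth


def generate_lfq(model: LFQModel) -> tuple[LFQTable, pd.DataFrame]:
    """Generate a two-group LFQ protein-groups table with planted effects.

    Returns (table, ground truth).  The truth DataFrame has one row per
    protein with ``is_hit`` and the planted log2 effect.  Intensities
    are linear scale with 0 for dropout, matching MaxQuant output.
    """
    rng = np.random.default_rng(model.seed)
    n, reps = model.n_proteins, model.n_replicates
    base = rng.normal(model.base_mean, model.base_sd, size=n)
    is_hit = np.zeros(n, dtype=bool)
    is_hit[: model.n_hits] = True

    samples = ([f"{model.group_a}_{r + 1}" for r in range(reps)]
               + [f"{model.group_b}_{r + 1}" for r in range(reps)])
    log2 = np.empty((n, 2 * reps))
    for j in range(2 * reps):
        group_a = j < reps
        mean = base + (model.effect * is_hit if group_a else 0.0)
        log2[:, j] = rng.normal(mean, model.noise_sd)

    # intensity-dependent dropout: low-abundance values vanish more often
    p_drop = model.dropout_max / (
        1.0 + np.exp((log2 - model.dropout_midpoint) / model.dropout_scale)
    )
    dropped = rng.random(size=log2.shape) < p_drop
    intensities = np.where(dropped, 0.0, np.exp2(log2))

    peptides = 1 + rng.poisson(max(model.peptide_mean - 1.0, 0.0), size=n)
    width = len(str(n))
    ids = [f"P{i + 1:0{width}d}" for i in range(n)]
    df = pd.DataFrame({
        "Protein IDs": ids,
        "Gene names": [f"GENE{i + 1}" for i in range(n)],
        "Peptides": peptides,
        "Reverse": "",
        "Potential contaminant": "",
        "Only identified by site": "",
    })
    for j, s in enumerate(samples):
        df[LFQ_PREFIX + s] = intensities[:, j]
    df["flagged"] = False
    groups = {model.group_a: samples[:reps], model.group_b: samples[reps:]}
    truth = pd.DataFrame({
        "protein": ids,
        "is_hit": is_hit,
        "planted_effect": np.where(is_hit, model.effect, 0.0),
        "base_log2": base,
    })
    return LFQTable(data=df, groups=groups), truth
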