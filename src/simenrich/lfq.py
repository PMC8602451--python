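"""Perseus-style differential enrichment of label-free quantification data.

Works on a MaxQuant-like protein-groups table (tab-separated, one
``LFQ intensity <sample>`` column per run).  The stages mirror the
conventional label-free workflow for a two-group pulldown design:

1. drop decoy / contaminant / only-identified-by-site rows, require a
   minimum peptide count and a minimum number of valid (non-missing)
   intensities in at least one group;
2. log2-transform, optionally center per-sample medians, and impute
   missing values from a downshifted normal distribution (per-sample
   mean − 1.8 SD, width 0.3 SD by default) — modelling the
   missing-not-at-random dropout of low-abundance proteins;
3. per protein, a two-sided two-sample Student's t-test between groups
   and the difference of group mean log2 intensities;
4. classification: high-confidence when |log2 difference| > 1 OR
   p < 0.05 (the OR rule; an AND variant is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LFQTable",
    "load_protein_groups",
    "filter_proteins",
    "transform_normalize_impute",
    "test_and_classify",
]

LFQ_PREFIX = "LFQ intensity "
FLAG_COLUMNS = ("Reverse", "Potential contaminant", "Only identified by site")


@dataclass
class LFQTable:
    """Protein-group intensities plus sample-to-group assignment.

    ``data`` holds one row per protein group; intensity columns are
    named ``LFQ intensity <sample>``; zero or NaN intensities mean
    missing (until imputation).  ``groups`` maps each of the two group
    labels to its sample names.  ``log_scale`` records whether the
    intensity columns are already log2.
    """

    data: pd.DataFrame
    groups: dict[str, list[str]]
    log_scale: bool = False
    id_column: str = "Protein IDs"
    # per-group counts of non-missing intensities, captured before imputation
    valid_counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.groups) != 2:
            raise ValueError("exactly two groups are required")
        seen: set[str] = set()
        for g, samples in self.groups.items():
            for s in samples:
                if s in seen:
                    raise ValueError(f"sample {s!r} assigned to more than one group")
                seen.add(s)
                if LFQ_PREFIX + s not in self.data.columns:
                    raise ValueError(f"missing column {LFQ_PREFIX + s!r}")

    @property
    def sample_columns(self) -> list[str]:
        return [LFQ_PREFIX + s for g in self.groups.values() for s in g]

    def group_columns(self, group: str) -> list[str]:
        return [LFQ_PREFIX + s for s in self.groups[group]]

    def intensities(self) -> pd.DataFrame:
        return self.data[self.sample_columns]

    def __len__(self) -> int:
        return len(self.data)


def load_protein_groups(path: str | Path,
                        groups: Mapping[str, Sequence[str]]) -> LFQTable:
    """Load a MaxQuant protein-groups TSV and assign samples to groups.

    Rows marked ``+`` in Reverse / Potential contaminant / Only
    identified by site are kept but flagged (``flagged`` column); the
    filter stage removes them.

    Raises
    ------
    ValueError
        If no ``LFQ intensity`` columns are present or an intensity
        cell is non-numeric (the error names the row and column).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    lfq_cols = [c for c in df.columns if c.startswith(LFQ_PREFIX)]
    if not lfq_cols:
        raise ValueError(f"{path}: no '{LFQ_PREFIX}<sample>' columns found")
    for col in lfq_cols:
        try:
            df[col] = pd.to_numeric(df[col].replace("", "0"))
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col].replace("", "0"),
                                         errors="coerce").isna()][0]
            raise ValueError(
                f"{path}: non-numeric intensity in column {col!r}, row {bad}"
            ) from None
    if "Peptides" in df.columns:
        df["Peptides"] = pd.to_numeric(df["Peptides"], errors="coerce").fillna(0).astype(int)
    flagged = np.zeros(len(df), dtype=bool)
    for col in FLAG_COLUMNS:
        if col in df.columns:
            flagged |= (df[col].astype(str).str.strip() == "+").to_numpy()
    df = df.copy()
    df["flagged"] = flagged
    table = LFQTable(data=df, groups={g: list(s) for g, s in groups.items()})
    return table


def filter_proteins(table: LFQTable, min_peptides: int = 2,
                    min_valid: int = 2) -> LFQTable:
    """Apply the identification filters.

    Keeps proteins that are unflagged, have at least ``min_peptides``
    peptides, and at least ``min_valid`` non-missing intensities in at
    least one of the two groups (presence in one group only is enough:
    on/off proteins are exactly the interesting ones in a pulldown).
    """
    df = table.data
    keep = ~df["flagged"].to_numpy() if "flagged" in df.columns else np.ones(len(df), bool)
    if "Peptides" in df.columns:
        keep &= (df["Peptides"] >= min_peptides).to_numpy()
    valid_ok = np.zeros(len(df), dtype=bool)
    for g in table.groups:
        vals = df[table.group_columns(g)].to_numpy(dtype=float)
        n_valid = np.sum(~_missing_mask(vals, table.log_scale), axis=1)
        valid_ok |= n_valid >= min_valid
    keep &= valid_ok
    out = df.loc[keep].reset_index(drop=True)
    return replace(table, data=out)


def _missing_mask(values: np.ndarray, log_scale: bool) -> np.ndarray:
    if log_scale:
        return ~np.isfinite(values)
    return ~np.isfinite(values) | (values <= 0)


def transform_normalize_impute(table: LFQTable,
                               median_normalize: bool = False,
                               impute_width: float = 0.3,
                               impute_shift: float = 1.8,
                               seed: int | None = None) -> LFQTable:
    """Log2-transform, optionally median-center, and impute missing values.

    Missing entries of each sample are replaced by draws from a normal
    distribution with mean ``sample_mean − impute_shift × sample_SD``
    and SD ``impute_width × sample_SD`` (downshifted imputation),
    seeded for reproducibility.  Median normalization centers every
    sample's median on the across-sample global median.

    Raises
    ------
    ValueError
        If any sample has fewer than 2 valid values (its SD, hence the
        imputation distribution, is undefined).
    """
    if table.log_scale:
        raise ValueError("table is already log2-transformed")
    rng = np.random.default_rng(seed)
    df = table.data.copy()
    cols = table.sample_columns
    mat = df[cols].to_numpy(dtype=float)
    missing = _missing_mask(mat, log_scale=False)
    valid_counts = pd.DataFrame({
        g: np.sum(~_missing_mask(df[table.group_columns(g)].to_numpy(dtype=float),
                                 log_scale=False), axis=1)
        for g in table.groups
    })
    with np.errstate(divide="ignore", invalid="ignore"):
        log2 = np.where(missing, np.nan, np.log2(np.where(missing, 1.0, mat)))

    if median_normalize:
        sample_medians = np.nanmedian(log2, axis=0)
        target = np.median(sample_medians)
        log2 = log2 - sample_medians[None, :] + target

    for j, col in enumerate(cols):
        col_vals = log2[:, j]
        obs = col_vals[np.isfinite(col_vals)]
        if obs.size < 2:
            raise ValueError(f"sample {col!r} has fewer than 2 valid values")
        mu, sd = float(obs.mean()), float(obs.std(ddof=1))
        miss = ~np.isfinite(col_vals)
        if miss.any():
            col_vals[miss] = rng.normal(mu - impute_shift * sd,
                                        impute_width * sd, size=int(miss.sum()))
        log2[:, j] = col_vals

    df[cols] = log2
    return replace(table, data=df, log_scale=True, valid_counts=valid_counts)


def test_and_classify(table: LFQTable, d_cut: float = 1.0, p_cut: float = 0.05,
                      rule: str = "or", equal_var: bool = True) -> pd.DataFrame:
    """Per-protein two-sample t-test and high-confidence classification.

    The log2 difference is group A minus group B (first minus second
    group in the table's mapping).  Under the default OR rule a protein
    is high-confidence when |log2 difference| > ``d_cut`` or
    p < ``p_cut``; ``rule="and"`` requires both.  ``equal_var=False``
    switches to Welch's t-test.

    Returns a DataFrame with columns: protein id, per-group mean log2
    intensity and valid counts, log2_difference, t_statistic, p_value,
    neg_log10_p, high_confidence, direction.
    """
    if not table.log_scale:
        raise ValueError("run transform_normalize_impute first (table not log2)")
    if rule not in ("or", "and"):
        raise ValueError(f"unknown classification rule {rule!r}")
    (ga, sa), (gb, sb) = table.groups.items()
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = table.data[table.group_columns(ga)].to_numpy(dtype=float)
    b = table.data[table.group_columns(gb)].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    diff = mean_a - mean_b
    t_stat, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance, identical groups
    t_stat = np.where(np.isnan(t_stat), 0.0, t_stat)
    if rule == "or":
        high = (np.abs(diff) > d_cut) | (p < p_cut)
    else:
        high = (np.abs(diff) > d_cut) & (p < p_cut)
    ids = (table.data[table.id_column]
           if table.id_column in table.data.columns
           else pd.Series(np.arange(len(table.data)).astype(str)))
    out = pd.DataFrame({
        "protein": ids.to_numpy(),
        f"mean_log2_{ga}": mean_a,
        f"mean_log2_{gb}": mean_b,
        f"n_valid_{ga}": (table.valid_counts[ga].to_numpy()
                          if table.valid_counts is not None
                          else a.shape[1] - np.isnan(a).sum(axis=1)),
        f"n_valid_{gb}": (table.valid_counts[gb].to_numpy()
                          if table.valid_counts is not None
                          else b.shape[1] - np.isnan(b).sum(axis=1)),
        "log2_difference": diff,
        "t_statistic": t_stat,
        "p_value": p,
        "neg_log10_p": -np.log10(np.clip(p, 1e-300, None)),
        "high_confidence": high,
        "direction": np.where(diff > 0, ga, np.where(diff < 0, gb, "none")),
    })
    if "Gene names" in table.data.columns:
        out.insert(1, "gene", table.data["Gene names"].to_numpy())
    return out
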