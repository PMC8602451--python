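"""Model / Results objects tying the pipeline together.

Two model classes, in the statsmodels idiom — a model is built from
data, ``fit()`` returns a results object carrying estimates,
uncertainties and a ``summary()`` table:

:class:`SimEnrichment`
    SIM-density enrichment of a protein list against a resampled
    proteome null.
:class:`LFQDifferential`
    Perseus-style two-group differential enrichment of a label-free
    protein-groups table.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import lfq as _lfq
from .enrichment import (
    NullConfig,
    RoutConfig,
    build_null,
    enrichment as _compute_enrichment,
    proteome_profiles,
)
from .io import Proteome, ProteinList, read_fasta, read_protein_list
from .scan import annotate_flanks, list_statistics, scan_sequence

__all__ = [
    "SimEnrichment",
    "SimEnrichmentResults",
    "LFQDifferential",
    "LFQDifferentialResults",
]


class SimEnrichment:
    """SIM enrichment of a query protein list against a proteome null.

    Parameters
    ----------
    proteome
        The sampling frame (e.g. the reviewed human proteome).
    query
        The protein list under test (resolved :class:`ProteinList`).
    mode
        SIM counting mode, ``"collapsed"`` (default) or ``"all_matches"``.
    """

    def __init__(self, proteome: Proteome, query: ProteinList,
                 mode: str = "collapsed"):
        missing = [a for a in query.members if a not in proteome]
        if missing:
            raise ValueError(f"query members not in proteome: {missing[:5]}...")
        self.proteome = proteome
        self.query = query
        self.mode = mode
        self._profiles = None  # lazy per-proteome scan cache

    @classmethod
    def from_files(cls, proteome_path: str | Path, list_path: str | Path,
                   mode: str = "collapsed") -> "SimEnrichment":
        proteome = read_fasta(proteome_path)
        query = read_protein_list(list_path, proteome)
        return cls(proteome, query, mode=mode)

    @property
    def profiles(self):
        if self._profiles is None:
            self._profiles = proteome_profiles(self.proteome, mode=self.mode)
        return self._profiles

    def fit(self, n_lists: int = 1000, seed: int = 0, list_size: int | None = None,
            q: float = 0.01, exclude_query: bool = False,
            min_length: int = 0, rout_method: str = "lorentzian"
            ) -> "SimEnrichmentResults":
        """Build the null and compute fold-enrichment and empirical p.

        ``list_size`` defaults to the query-list size, matching the
        resampling design (random lists of the same size as the query).
        """
        k = list_size if list_size is not None else len(self.query)
        config = NullConfig(n_lists=n_lists, list_size=k, seed=seed,
                                 exclude_query=exclude_query,
                                 min_length=min_length)
        rout = RoutConfig(q=q, method=rout_method)
        profiles = self.profiles
        by_acc = {p.accession: p for p in profiles}
        observed = list_statistics([by_acc[a] for a in self.query.members],
                                   label=self.query.label)
        null = build_null(self.proteome, config=config, rout=rout,
                               mode=self.mode, query=self.query,
                               profiles=profiles)
        result = _compute_enrichment(observed, null)
        return SimEnrichmentResults(self, observed, null, result)


class SimEnrichmentResults:
    """Fitted SIM-enrichment results: observed statistics, null, enrichment."""

    def __init__(self, model: SimEnrichment, observed, null, result):
        self.model = model
        self.observed = observed
        self.null = null
        self.result = result

    # convenience accessors
    @property
    def fold_enrichment(self) -> float:
        return self.result.fold_enrichment

    @property
    def empirical_p(self) -> float:
        return self.result.empirical_p

    @property
    def observed_staa(self) -> float:
        return self.observed.staa_value

    @property
    def null_median(self) -> float:
        return self.null.null_median

    def matches(self, flank_window: int = 4) -> pd.DataFrame:
        """Per-match table for the query proteins (1-based start for reports)."""
        rows = []
        for acc in self.model.query.members:
            seq = self.model.proteome[acc].sequence
            for m in annotate_flanks(seq, scan_sequence(seq, mode=self.model.mode,
                                                        accession=acc),
                                     window=flank_window):
                rows.append({
                    "accession": acc,
                    "start_1based": m.start + 1,
                    "end": m.end,
                    "pattern_class": m.pattern_class.value,
                    "subsequence": m.subsequence,
                    "acidic_or_ser_flank": m.acidic_or_ser_flank,
                })
        return pd.DataFrame(rows, columns=["accession", "start_1based", "end",
                                           "pattern_class", "subsequence",
                                           "acidic_or_ser_flank"])

    def flank_fraction(self, flank_window: int = 4) -> float:
        """Fraction of query SIMs with an acidic/Ser flank within the window."""
        df = self.matches(flank_window=flank_window)
        if df.empty:
            return float("nan")
        return float(df["acidic_or_ser_flank"].mean())

    def null_table(self) -> pd.DataFrame:
        """Per-random-list statistics with outlier flags."""
        return pd.DataFrame({
            "list_index": np.arange(1, len(self.null.list_stats) + 1),
            "pct_single": [s.pct_single for s in self.null.list_stats],
            "pct_multiple": [s.pct_multiple for s in self.null.list_stats],
            "staa": self.null.staa_values,
            "outlier": self.null.outlier_flags,
        })

    def summary(self) -> str:
        r, n = self.result, self.null
        lines = [
            "SIM enrichment analysis",
            "=" * 60,
            f"query list:            {self.observed.label} "
            f"(n={self.observed.n_proteins})",
            f"proteome:              {self.model.proteome.source_label} "
            f"({len(self.model.proteome)} proteins)",
            f"counting mode:         {self.model.mode}",
            f"random lists:          {n.config.n_lists} x {n.config.list_size} "
            f"(seed {n.config.seed})",
            f"ROUT outliers removed: {n.n_outliers} (Q={n.rout.q:g})",
            f"normality (log2 null): K2={n.normality.k2:.3f}, "
            f"p={n.normality.p_value:.3g} (n={n.normality.n})",
            "-" * 60,
            f"observed STAA:         {r.observed_staa:.2f} "
            f"(log2 {np.log2(r.observed_staa):.2f})",
            f"null median STAA:      {r.null_median:.2f} "
            f"(log2 {np.log2(r.null_median):.2f})",
            f"fold enrichment:       {r.fold_enrichment:.2f}",
            f"empirical p:           {r.p_label} "
            f"({r.exceed_count}/{r.n_retained} null lists >= observed)",
            f"% single SIM:          {r.observed_pct_single:.2f} observed vs "
            f"{r.null_pct_single:.2f} null median",
            f"% multiple SIM:        {r.observed_pct_multiple:.2f} observed vs "
            f"{r.null_pct_multiple:.2f} null median",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        r, n = self.result, self.null
        return {
            "label": self.observed.label,
            "n_query": self.observed.n_proteins,
            "mode": self.model.mode,
            "n_lists": n.config.n_lists,
            "list_size": n.config.list_size,
            "seed": n.config.seed,
            "rout_q": n.rout.q,
            "n_outliers": n.n_outliers,
            "normality_k2": n.normality.k2,
            "normality_p": n.normality.p_value,
            "observed_staa": r.observed_staa,
            "null_median_staa": r.null_median,
            "fold_enrichment": r.fold_enrichment,
            "empirical_p": r.empirical_p,
            "empirical_p_is_upper_bound": r.is_upper_bound,
            "observed_pct_single": r.observed_pct_single,
            "observed_pct_multiple": r.observed_pct_multiple,
            "null_pct_single_median": r.null_pct_single,
            "null_pct_multiple_median": r.null_pct_multiple,
        }

    def plot_null(self, ax=None):
        """Violin of the null STAA values with the observed value marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 5))
        ax.violinplot(self.null.retained_values, showmedians=True)
        ax.axhline(self.observed_staa, color="tab:blue", ls=":",
                   label=f"observed ({self.observed_staa:.2f})")
        ax.axhline(self.null_median, color="k", ls=":",
                   label=f"null median ({self.null_median:.2f})")
        ax.set_ylabel("STAA (SIMs per 1000 aa)")
        ax.set_xticks([])
        ax.legend(frameon=False, fontsize=8)
        return ax


class LFQDifferential:
    """Two-group differential enrichment of a label-free protein-groups table.

    Parameters
    ----------
    table
        :class:`~simenrich.lfq.LFQTable` (linear intensities, missing as
        0/NaN) with its two-group sample assignment.
    """

    def __init__(self, table: _lfq.LFQTable):
        self.table = table

    @classmethod
    def from_protein_groups(cls, path: str | Path,
                            groups: Mapping[str, Sequence[str]]
                            ) -> "LFQDifferential":
        return cls(_lfq.load_protein_groups(path, groups))

    def fit(self, min_peptides: int = 2, min_valid: int = 2,
            median_normalize: bool = False, impute_width: float = 0.3,
            impute_shift: float = 1.8, seed: int | None = 0,
            d_cut: float = 1.0, p_cut: float = 0.05, rule: str = "or",
            equal_var: bool = True) -> "LFQDifferentialResults":
        """Filter, transform/impute, test and classify; returns results."""
        filtered = _lfq.filter_proteins(self.table, min_peptides=min_peptides,
                                        min_valid=min_valid)
        processed = _lfq.transform_normalize_impute(
            filtered, median_normalize=median_normalize,
            impute_width=impute_width, impute_shift=impute_shift, seed=seed)
        table = _lfq.test_and_classify(processed, d_cut=d_cut, p_cut=p_cut,
                                       rule=rule, equal_var=equal_var)
        params = dict(min_peptides=min_peptides, min_valid=min_valid,
                      median_normalize=median_normalize,
                      impute_width=impute_width, impute_shift=impute_shift,
                      seed=seed, d_cut=d_cut, p_cut=p_cut, rule=rule,
                      equal_var=equal_var)
        return LFQDifferentialResults(self, processed, table, params)


class LFQDifferentialResults:
    """Per-protein differential results with volcano-plot columns."""

    def __init__(self, model: LFQDifferential, processed: _lfq.LFQTable,
                 table: pd.DataFrame, params: dict):
        self.model = model
        self.processed = processed
        self.table = table
        self.params = params

    @property
    def high_confidence(self) -> pd.DataFrame:
        return self.table[self.table["high_confidence"]]

    def summary(self) -> str:
        ga, gb = self.model.table.groups
        n = len(self.table)
        n_hc = int(self.table["high_confidence"].sum())
        n_up = int(((self.table["log2_difference"] > 0)
                    & self.table["high_confidence"]).sum())
        lines = [
            "Label-free differential enrichment",
            "=" * 60,
            f"comparison:          {ga} vs {gb} "
            f"({len(self.model.table.groups[ga])} vs "
            f"{len(self.model.table.groups[gb])} replicates)",
            f"proteins loaded:     {len(self.model.table)}",
            f"proteins tested:     {n} (>= {self.params['min_peptides']} peptides, "
            f">= {self.params['min_valid']} valid in a group)",
            f"imputation:          width {self.params['impute_width']} SD, "
            f"shift {self.params['impute_shift']} SD (seed "
            f"{self.params['seed']})",
            f"classification:      |log2 diff| > {self.params['d_cut']:g} "
            f"{self.params['rule'].upper()} p < {self.params['p_cut']:g}",
            "-" * 60,
            f"high-confidence:     {n_hc} ({n_up} enriched in {ga}, "
            f"{n_hc - n_up} in {gb})",
        ]
        return "\n".join(lines)

    def plot_volcano(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        hc = self.table["high_confidence"]
        ax.scatter(self.table.loc[~hc, "log2_difference"],
                   self.table.loc[~hc, "neg_log10_p"], s=8, c="0.7")
        ax.scatter(self.table.loc[hc, "log2_difference"],
                   self.table.loc[hc, "neg_log10_p"], s=8, c="tab:orange")
        ax.axhline(-np.log10(self.params["p_cut"]), ls=":", c="k", lw=0.8)
        for x in (-self.params["d_cut"], self.params["d_cut"]):
            ax.axvline(x, ls=":", c="k", lw=0.8)
        ax.set_xlabel("log2 difference")
        ax.set_ylabel("-log10 p")
        return ax
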