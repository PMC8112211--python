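"""Signed transcriptional signatures for disease cohorts and compound perturbations.

A *signed signature* assigns each gene a direction (+1 up, -1 down, 0 inactive),
an effect-size magnitude, and an integer support (how many experiments or cell
lines agree on the call).  Three constructors are provided:

``compute_disease_signature``
    Differential expression between case and control samples of an RNA-seq
    cohort (Welch t-test on log2(x+1), Benjamini-Hochberg FDR), thresholded on
    |log2FC| and adjusted p.

``compute_tcs``
    Transcriptional consensus signature of a compound across cell lines: per
    cell line the sign of the median differential score over that line's
    experiments, then a strict majority vote across cell lines.  The support
    counts agreeing cell lines and is therefore capped at the number of cell
    lines used.

``compute_reference_signature``
    Robust signature of a reference drug within a chosen set of cell-line
    contexts: a gene is active only if the same sign recurs in at least a given
    fraction of the filtered experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionCohort",
    "SignedSignature",
    "PerturbationPanel",
    "compute_disease_signature",
    "compute_tcs",
    "compute_reference_signature",
]

CASE = "case"
CONTROL = "control"


@dataclass
class ExpressionCohort:
    """Gene x sample expression matrix with per-sample condition labels.

    ``values``: DataFrame, rows = genes, columns = samples.
    ``conditions``: Series mapping sample id -> {"case", "control"}.
    ``units``: free-text description of the measurement scale ("counts" for
    raw RNA-seq counts, which is what the default synthetic cohorts emit).
    """

    values: pd.DataFrame
    conditions: pd.Series
    units: str = "counts"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene IDs: {list(dups[:5])}")
        self.conditions = self.conditions.reindex(self.values.columns)
        if self.conditions.isna().any():
            missing = self.conditions.index[self.conditions.isna()]
            raise ValueError(f"samples without condition label: {list(missing[:5])}")
        bad = set(self.conditions.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def samples(self, condition: str) -> pd.Index:
        return self.conditions.index[self.conditions == condition]


@dataclass
class SignedSignature:
    """Per-gene signed call with magnitude and consensus support.

    ``frame`` is indexed by gene with columns ``direction`` (int, in
    {-1, 0, +1}), ``magnitude`` (float, sign agrees with direction when
    direction != 0) and ``support`` (non-negative int).  Genes carried with
    direction 0 define the signature's universe without being active.
    """

    frame: pd.DataFrame
    name: str = "signature"

    def __post_init__(self) -> None:
        required = {"direction", "magnitude", "support"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"signature frame needs columns {sorted(required)}")
        if self.frame.index.duplicated().any():
            raise ValueError("duplicate gene IDs in signature")
        d = self.frame["direction"]
        if not d.isin([-1, 0, 1]).all():
            raise ValueError("direction must be in {-1, 0, +1}")
        active = d != 0
        mag = self.frame.loc[active, "magnitude"]
        if ((np.sign(mag) != d[active]) & (mag != 0)).any():
            raise ValueError("magnitude sign disagrees with direction")
        if (self.frame["support"] < 0).any():
            raise ValueError("support must be non-negative")

    @classmethod
    def from_arrays(
        cls,
        genes: Iterable[str],
        direction: np.ndarray,
        magnitude: np.ndarray,
        support: np.ndarray,
        name: str = "signature",
    ) -> "SignedSignature":
        frame = pd.DataFrame(
            {
                "direction": np.asarray(direction, dtype=int),
                "magnitude": np.asarray(magnitude, dtype=float),
                "support": np.asarray(support, dtype=int),
            },
            index=pd.Index(genes, name="gene"),
        )
        return cls(frame, name=name)

    @property
    def genes(self) -> pd.Index:
        return self.frame.index

    @property
    def direction(self) -> pd.Series:
        return self.frame["direction"]

    @property
    def n_up(self) -> int:
        return int((self.frame["direction"] == 1).sum())

    @property
    def n_down(self) -> int:
        return int((self.frame["direction"] == -1).sum())

    @property
    def n_active(self) -> int:
        return self.n_up + self.n_down

    def active_genes(self) -> pd.Index:
        return self.frame.index[self.frame["direction"] != 0]

    def restrict(self, genes: Iterable[str]) -> "SignedSignature":
        keep = self.frame.index.intersection(pd.Index(genes))
        return SignedSignature(self.frame.loc[keep], name=self.name)

    def direction_on(self, genes: pd.Index) -> np.ndarray:
        """Directions on an arbitrary gene list; genes outside the universe map to 0."""
        return (
            self.frame["direction"].reindex(genes, fill_value=0).to_numpy(dtype=int)
        )


@dataclass
class PerturbationPanel:
    """Differential-expression profiles per (compound, cell line, experiment).

    ``scores``: DataFrame with a 3-level MultiIndex (compound, cell_line,
    experiment) over rows and genes as columns; values are signed differential
    scores on a shared gene universe (level-4 style robust z-scores).
    """

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        if self.scores.index.nlevels != 3:
            raise ValueError("panel index must be (compound, cell_line, experiment)")
        self.scores.index = self.scores.index.set_names(
            ["compound", "cell_line", "experiment"]
        )
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("panel scores must be finite")
        for level in ("compound", "cell_line"):
            ids = self.scores.index.get_level_values(level)
            if (ids.astype(str) == "").any():
                raise ValueError(f"empty {level} id in panel")

    @property
    def genes(self) -> pd.Index:
        return self.scores.columns

    @property
    def compounds(self) -> list:
        return sorted(self.scores.index.get_level_values("compound").unique())

    def records_for(self, compound: str) -> pd.DataFrame:
        if compound not in self.scores.index.get_level_values("compound"):
            raise KeyError(f"compound {compound!r} not in panel")
        return self.scores.xs(compound, level="compound")


def compute_disease_signature(
    cohort: ExpressionCohort,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.1,
) -> SignedSignature:
    """Case-vs-control differential-expression signature.

    Values are transformed to log2(x+1); a two-sided Welch t-test per gene is
    adjusted by Benjamini-Hochberg; log2 fold change is the difference of
    condition means of the transformed values.  A gene is active iff
    |log2FC| > ``lfc_threshold`` (strict) and adjusted p < ``fdr_threshold``
    (strict).  Genes constant across all samples are excluded with a warning.
    """
    if lfc_threshold < 0:
        raise ValueError("lfc_threshold must be non-negative")
    if not 0 < fdr_threshold <= 1:
        raise ValueError("fdr_threshold must be in (0, 1]")
    case_ids = cohort.samples(CASE)
    ctrl_ids = cohort.samples(CONTROL)
    for label, ids in ((CASE, case_ids), (CONTROL, ctrl_ids)):
        if len(ids) == 0:
            raise ValueError(f"condition {label!r} absent from cohort")
        if len(ids) < 2:
            raise ValueError(f"need >=2 {label!r} samples, got {len(ids)}")
    x = cohort.values.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    logx = np.log2(x + 1.0)
    constant = np.ptp(logx, axis=1) == 0
    if constant.any():
        warnings.warn(
            f"excluding {int(constant.sum())} constant gene(s) from DE testing",
            stacklevel=2,
        )
    keep = ~constant
    genes = cohort.genes[keep]
    case = logx[keep][:, cohort.values.columns.get_indexer(case_ids)]
    ctrl = logx[keep][:, cohort.values.columns.get_indexer(ctrl_ids)]
    lfc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, pvals = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    # zero within-arm variance with unequal means gives p=0; equal means p=1
    pvals = np.where(np.isnan(pvals), np.where(lfc == 0, 1.0, 0.0), pvals)
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    active = (np.abs(lfc) > lfc_threshold) & (padj < fdr_threshold)
    direction = np.where(active, np.sign(lfc).astype(int), 0)
    support = active.astype(int)
    sig = SignedSignature.from_arrays(genes, direction, lfc, support, name="disease")
    return sig


def _majority_call(n_pos: np.ndarray, n_neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strict majority direction and agreeing count; exact ties -> inactive."""
    direction = np.zeros(n_pos.shape, dtype=int)
    direction[n_pos > n_neg] = 1
    direction[n_neg > n_pos] = -1
    support = np.where(direction == 1, n_pos, np.where(direction == -1, n_neg, 0))
    return direction, support.astype(int)


def compute_tcs(
    panel: PerturbationPanel,
    compound: str,
    per_experiment_threshold: float = 0.0,
) -> SignedSignature:
    """Transcriptional consensus signature of a compound across cell lines.

    Per cell line, a gene's call is the sign of the median differential score
    over that line's experiments, zeroed when |median| < threshold.  The TCS
    direction is the strict-majority sign over calling cell lines; support is
    the number of cell lines sharing that sign (max = number of cell lines).
    """
    if per_experiment_threshold < 0:
        raise ValueError("per_experiment_threshold must be non-negative")
    records = panel.records_for(compound)
    medians = records.groupby(level="cell_line", sort=True).median()
    m = medians.to_numpy(dtype=float)
    calls = np.sign(m).astype(int)
    calls[np.abs(m) < per_experiment_threshold] = 0
    n_pos = (calls == 1).sum(axis=0)
    n_neg = (calls == -1).sum(axis=0)
    direction, support = _majority_call(n_pos, n_neg)
    # magnitude: mean of cell-line medians among the agreeing cell lines
    magnitude = np.zeros(m.shape[1])
    for s in (1, -1):
        cols = direction == s
        if cols.any():
            agree = (calls[:, cols] == s).astype(float)
            magnitude[cols] = (m[:, cols] * agree).sum(axis=0) / agree.sum(axis=0)
    return SignedSignature.from_arrays(
        panel.genes, direction, magnitude, support, name=str(compound)
    )


def compute_reference_signature(
    panel: PerturbationPanel,
    compound: str,
    cell_line_filter: Iterable[str] | None = None,
    min_fraction: float = 0.5,
    per_experiment_threshold: float = 0.0,
) -> SignedSignature:
    """Robust reference signature over a filtered set of cell-line contexts.

    A gene is active iff one sign recurs in >= ``min_fraction`` of the filtered
    experiments; if both signs reach the fraction (possible when
    ``min_fraction`` <= 0.5) the gene is conservatively inactive.  Support is
    the number of agreeing experiments.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    records = panel.records_for(compound)
    if cell_line_filter is not None:
        wanted = set(cell_line_filter)
        mask = records.index.get_level_values("cell_line").isin(wanted)
        records = records[mask]
        if records.empty:
            raise ValueError(
                f"compound {compound!r} has no experiments in cell lines {sorted(wanted)}"
            )
    m = records.to_numpy(dtype=float)
    calls = np.sign(m).astype(int)
    calls[np.abs(m) < per_experiment_threshold] = 0
    n_exp = m.shape[0]
    n_pos = (calls == 1).sum(axis=0)
    n_neg = (calls == -1).sum(axis=0)
    pos_ok = n_pos / n_exp >= min_fraction
    neg_ok = n_neg / n_exp >= min_fraction
    direction = np.where(pos_ok & ~neg_ok, 1, np.where(neg_ok & ~pos_ok, -1, 0))
    support = np.where(direction == 1, n_pos, np.where(direction == -1, n_neg, 0))
    magnitude = np.zeros(m.shape[1])
    for s in (1, -1):
        cols = direction == s
        if cols.any():
            agree = (calls[:, cols] == s).astype(float)
            magnitude[cols] = (m[:, cols] * agree).sum(axis=0) / agree.sum(axis=0)
    return SignedSignature.from_arrays(
        panel.genes, direction, magnitude, support.astype(int), name=str(compound)
    )
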