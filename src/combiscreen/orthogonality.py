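"""Orthogonality scoring of candidate compounds against a reference drug.

For a candidate signature ``z``, a reference signature ``r`` and a disease
signature ``d``, two ratios are computed over sign products:

* concordance ratio CR — among genes active in both z and r, the share whose
  directions agree (normalized mode), or the literal same:opposite count ratio
  (as_printed mode);
* disease discordance ratio DR — among disease-signature genes *missing from
  the reference* (r_i = 0) and active in z, the share the candidate reverses.

The orthogonality score OS = sqrt((1-CR)^2 + DR^2) is maximal for compounds
that are transcriptionally unlike the reference (low CR) while reversing the
disease genes the reference does not cover (high DR) — the "upper-left corner"
of a CR-vs-DR scatter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .signatures import PerturbationPanel, SignedSignature, compute_tcs

__all__ = [
    "OrthogonalityRecord",
    "CorrelationNetwork",
    "RankingResult",
    "concordance_ratio",
    "discordance_ratio",
    "orthogonality_score",
    "rank_candidates",
    "tcs_correlation_network",
]

NORMALIZED = "normalized"
AS_PRINTED = "as_printed"
_MODES = (NORMALIZED, AS_PRINTED)


@dataclass
class OrthogonalityRecord:
    compound: str
    reference: str
    cr: float
    dr: float
    os: float
    n_concordant: int
    n_discordant: int
    n_disease_only_concordant: int
    n_disease_only_discordant: int
    flagged: bool = False
    flag_reason: str = ""


def _check_mode(mode: str) -> None:
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")


def _ratio(n_hit: int, n_miss: int, mode: str) -> tuple[float, bool, str]:
    """(ratio, flagged, reason) for hit/miss counts under either mode."""
    if n_hit + n_miss == 0:
        return math.nan, True, "no eligible genes"
    if mode == NORMALIZED:
        return n_hit / (n_hit + n_miss), False, ""
    if n_miss == 0:
        return math.inf, True, "as_printed denominator zero"
    return n_hit / n_miss, False, ""


def concordance_ratio(
    z: SignedSignature, r: SignedSignature, mode: str = NORMALIZED
) -> tuple[float, dict]:
    """CR of candidate z against reference r over their shared gene universe.

    Counts genes with z_i*r_i != 0: ``n_same`` where the signs agree,
    ``n_opp`` where they oppose.  normalized: n_same/(n_same+n_opp);
    as_printed: n_same/n_opp (+inf sentinel, flagged, when n_opp = 0).
    """
    _check_mode(mode)
    shared = z.genes.intersection(r.genes)
    if len(shared) == 0:
        raise ValueError("gene universes of z and r do not intersect")
    if r.n_active == 0:
        raise ValueError("reference signature has no active genes")
    prod = z.direction_on(shared) * r.direction_on(shared)
    n_same = int((prod > 0).sum())
    n_opp = int((prod < 0).sum())
    cr, flagged, reason = _ratio(n_same, n_opp, mode)
    return cr, {
        "n_concordant": n_same,
        "n_discordant": n_opp,
        "flagged": flagged,
        "flag_reason": reason,
    }


def discordance_ratio(
    z: SignedSignature,
    d: SignedSignature,
    r: SignedSignature,
    mode: str = NORMALIZED,
) -> tuple[float, dict]:
    """DR of candidate z against disease d, restricted to genes absent from r.

    Eligible genes: shared between z and d, inactive in the reference
    (r_i = 0; genes outside r's universe count as inactive), with z_i*d_i != 0.
    ``n_disc`` counts reversals (z opposes d), ``n_conc`` mimicry.
    """
    _check_mode(mode)
    if d.n_active == 0:
        raise ValueError("disease signature has no active genes")
    shared = z.genes.intersection(d.genes)
    if len(shared) == 0:
        raise ValueError("gene universes of z and d do not intersect")
    r_dir = r.direction_on(shared)
    zd = z.direction_on(shared) * d.direction_on(shared)
    eligible = r_dir == 0
    n_disc = int(((zd < 0) & eligible).sum())
    n_conc = int(((zd > 0) & eligible).sum())
    dr, flagged, reason = _ratio(n_disc, n_conc, mode)
    return dr, {
        "n_disease_only_discordant": n_disc,
        "n_disease_only_concordant": n_conc,
        "flagged": flagged,
        "flag_reason": reason,
    }


def orthogonality_score(cr: float, dr: float) -> float:
    """OS = sqrt((1-CR)^2 + DR^2)."""
    if not (np.isfinite(cr) and np.isfinite(dr)):
        raise ValueError(f"CR and DR must be finite, got ({cr}, {dr})")
    return math.hypot(1.0 - cr, dr)


def score_compound(
    z: SignedSignature,
    disease: SignedSignature,
    reference: SignedSignature,
    mode: str = NORMALIZED,
) -> OrthogonalityRecord:
    """Full (CR, DR, OS) record for one candidate signature."""
    cr, cinfo = concordance_ratio(z, reference, mode)
    dr, dinfo = discordance_ratio(z, disease, reference, mode)
    flagged = cinfo["flagged"] or dinfo["flagged"]
    reason = "; ".join(x for x in (cinfo["flag_reason"], dinfo["flag_reason"]) if x)
    os_val = math.nan if flagged else orthogonality_score(cr, dr)
    return OrthogonalityRecord(
        compound=z.name,
        reference=reference.name,
        cr=cr,
        dr=dr,
        os=os_val,
        n_concordant=cinfo["n_concordant"],
        n_discordant=cinfo["n_discordant"],
        n_disease_only_concordant=dinfo["n_disease_only_concordant"],
        n_disease_only_discordant=dinfo["n_disease_only_discordant"],
        flagged=flagged,
        flag_reason=reason,
    )


@dataclass
class RankingResult:
    """Ordered orthogonality table for one reference drug."""

    reference: str
    table: pd.DataFrame  # all valid records, sorted
    top: pd.DataFrame  # head(top_k)
    flagged: pd.DataFrame  # undefined-ratio compounds, excluded from ranking

    @property
    def top_compounds(self) -> list:
        return list(self.top["compound"])


def rank_candidates(
    panel: PerturbationPanel,
    reference: str,
    disease: SignedSignature,
    top_k: int = 3,
    reference_signature: SignedSignature | None = None,
    mode: str = NORMALIZED,
    per_experiment_threshold: float = 0.0,
    tcs: dict[str, SignedSignature] | None = None,
) -> RankingResult:
    """Rank every panel compound (except the reference) by OS, descending.

    Ties break by higher DR, then lexicographic compound id.  Compounds with
    undefined CR or DR are excluded from the ranking and reported separately.
    ``reference_signature`` defaults to the reference compound's TCS; pass a
    robust reference signature (``compute_reference_signature``) for the
    study-style screen.  Precomputed TCSs can be supplied via ``tcs``.
    """
    if reference_signature is None:
        reference_signature = compute_tcs(panel, reference, per_experiment_threshold)
    if reference_signature.n_active == 0:
        raise ValueError(f"reference {reference!r} has an empty signature")
    records = []
    for compound in panel.compounds:
        if compound == reference:
            continue
        z = (
            tcs[compound]
            if tcs is not None and compound in tcs
            else compute_tcs(panel, compound, per_experiment_threshold)
        )
        rec = score_compound(z, disease, reference_signature, mode)
        rec.compound = str(compound)
        rec.reference = str(reference)
        records.append(rec)
    frame = pd.DataFrame([vars(r) for r in records])
    flagged = frame[frame["flagged"]].reset_index(drop=True)
    valid = frame[~frame["flagged"]].copy()
    valid = valid.sort_values(
        ["os", "dr", "compound"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    if top_k > len(valid):
        warnings.warn(
            f"top_k={top_k} exceeds {len(valid)} valid records; returning all",
            stacklevel=2,
        )
    return RankingResult(
        reference=str(reference),
        table=valid,
        top=valid.head(top_k).reset_index(drop=True),
        flagged=flagged,
    )


@dataclass
class CorrelationNetwork:
    """Compound-compound Pearson correlation graph with cluster labels."""

    graph: nx.Graph
    clusters: dict[str, int]
    threshold: float
    correlations: pd.DataFrame
    excluded: list = field(default_factory=list)


def tcs_correlation_network(
    tcs_set: dict[str, SignedSignature],
    threshold: float = 0.7,
    linkage_method: str = "average",
    use_support: bool = True,
) -> CorrelationNetwork:
    """Correlate consensus signatures and cluster compounds by mechanism.

    Pairwise Pearson r on direction*support vectors (or plain directions when
    ``use_support`` is False) over the shared gene universe; edges where
    r > threshold (strict); hierarchical clustering on distance 1 - r with the
    given linkage.  Zero-variance signatures are excluded with a warning.
    """
    if len(tcs_set) < 2:
        raise ValueError("need at least two compounds to correlate")
    names = sorted(tcs_set)
    shared = tcs_set[names[0]].genes
    for n in names[1:]:
        shared = shared.intersection(tcs_set[n].genes)
    if len(shared) == 0:
        raise ValueError("no shared gene universe across compounds")
    vectors, kept, excluded = [], [], []
    for n in names:
        sig = tcs_set[n]
        v = sig.direction_on(shared).astype(float)
        if use_support:
            v = v * sig.frame["support"].reindex(shared, fill_value=0).to_numpy()
        if np.ptp(v) == 0:
            excluded.append(n)
            continue
        vectors.append(v)
        kept.append(n)
    if excluded:
        warnings.warn(
            f"excluding zero-variance signatures: {excluded}", stacklevel=2
        )
    if len(kept) < 2:
        raise ValueError("fewer than two non-degenerate signatures")
    mat = np.corrcoef(np.vstack(vectors))
    corr = pd.DataFrame(mat, index=kept, columns=kept)
    graph = nx.Graph()
    graph.add_nodes_from(kept)
    for i, a in enumerate(kept):
        for j in range(i + 1, len(kept)):
            if mat[i, j] > threshold:
                graph.add_edge(a, kept[j], r=float(mat[i, j]))
    dist = 1.0 - mat
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)  # symmetrize fp noise
    z = linkage(squareform(dist, checks=False), method=linkage_method)
    labels = fcluster(z, t=1.0 - threshold, criterion="distance")
    clusters = {name: int(lab) for name, lab in zip(kept, labels)}
    return CorrelationNetwork(
        graph=graph,
        clusters=clusters,
        threshold=threshold,
        correlations=corr,
        excluded=excluded,
    )
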