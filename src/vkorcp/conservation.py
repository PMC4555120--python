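"""Empirical-Bayes per-site evolutionary-rate inference and nine-grade
conservation binning.

The rate prior is a discrete gamma (finer than the tree likelihood: 16
categories by default) with equal category weights; the posterior mean rate
of column i is

    r_i = sum_k r_k w_k L_i(r_k) / sum_k w_k L_i(r_k)

where L_i(r_k) is the pruning likelihood of the column with all branch
lengths scaled by r_k.  Rates are standardized across scored columns and
binned into nine equal-width grades over the observed score range: grade 9
is the most conserved (lowest rate), grade 1 the most variable.  Columns
that are entirely gaps in the scored subset get grade 0 ("absent").
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.special import logsumexp

from .io_formats import Alignment, MISSING
from .phylo import (
    _category_site_loglik,
    _TreeData,
    prune_to_taxa,
)
from .substitution import SubstitutionModel, discretize_gamma

#: Columns with less occupancy than this are scored but flagged low-confidence.
LOW_OCCUPANCY = 0.10


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column conservation summary for one set of sequences."""

    posterior_mean_rate: np.ndarray  # nan where absent
    normalized_score: np.ndarray  # zero mean / unit variance over scored cols
    grade: np.ndarray  # int, 1..9; 0 for absent columns
    low_confidence: np.ndarray  # bool, occupancy below LOW_OCCUPANCY

    def __len__(self) -> int:
        return len(self.grade)


def _occupancy(alignment: Alignment) -> np.ndarray:
    arr = np.array([list(r.residues) for r in alignment.records])
    present = ~np.isin(arr, sorted(MISSING))
    return present.mean(axis=0)


def site_rate_posteriors(
    alignment: Alignment,
    tree: dendropy.Tree,
    model: SubstitutionModel,
    n_cat: int = 16,
) -> np.ndarray:
    """Posterior mean rate per column under the discrete-gamma prior.

    The model must carry a gamma shape (the empirical-Bayes prior).  Columns
    with no observed residues have an undefined rate and are returned as
    NaN.  All defined values lie within [min rate, max rate] of the
    discretized prior.
    """
    if model.alpha is None:
        raise ValueError("rate inference needs a model with a gamma shape (alpha)")
    rates = discretize_gamma(model.alpha, n_cat)
    td = _TreeData(tree, alignment)
    cat_logs = _category_site_loglik(td, model, rates)  # (K, S)
    # equal prior weights cancel in the ratio
    log_norm = logsumexp(cat_logs, axis=0)
    with np.errstate(invalid="ignore"):
        post = np.exp(cat_logs - log_norm[None, :])
    mean = rates @ post
    occ = _occupancy(alignment)
    mean[occ == 0.0] = np.nan
    return mean


def grades_from_scores(posterior_rates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize rates and bin them into nine equal-width grades.

    Returns ``(normalized_score, grade)``.  The observed score range is
    partitioned into 9 equal-width bins; the lowest bin (most conserved)
    maps to grade 9 and the highest to grade 1.  If all scores coincide,
    every scored column gets the intermediate grade 5.  NaN rates (absent
    columns) map to grade 0.
    """
    rates = np.asarray(posterior_rates, dtype=float)
    if rates.size == 0:
        raise ValueError("no columns to grade")
    scored = np.isfinite(rates)
    if not scored.any():
        raise ValueError("no scored columns to grade")
    vals = rates[scored]
    sd = vals.std()
    scores = np.full(rates.shape, np.nan)
    if sd == 0:
        scores[scored] = 0.0
        grades = np.where(scored, 5, 0)
        return scores, grades.astype(int)
    scores[scored] = (rates[scored] - vals.mean()) / sd
    lo, hi = scores[scored].min(), scores[scored].max()
    width = (hi - lo) / 9.0
    # bin index 0 (lowest score = most conserved) -> grade 9
    idx = np.floor((scores[scored] - lo) / width).astype(int)
    idx = np.clip(idx, 0, 8)
    grades = np.zeros(rates.shape, dtype=int)
    grades[scored] = 9 - idx
    return scores, grades


def profile_from_rates(rates: np.ndarray, occupancy: np.ndarray) -> ConservationProfile:
    scores, grades = grades_from_scores(rates)
    low = (occupancy < LOW_OCCUPANCY) & (occupancy > 0)
    return ConservationProfile(rates, scores, grades, low)


def conservation_profile(
    alignment: Alignment,
    tree: dendropy.Tree,
    model: SubstitutionModel,
    n_cat: int = 16,
) -> ConservationProfile:
    """Rate inference plus grading over the whole alignment."""
    rates = site_rate_posteriors(alignment, tree, model, n_cat=n_cat)
    return profile_from_rates(rates, _occupancy(alignment))


def clade_profile(
    alignment: Alignment,
    tree: dendropy.Tree,
    clade_members,
    model: SubstitutionModel,
    n_cat: int = 16,
) -> ConservationProfile:
    """Conservation profile restricted to one clade.

    Rows are restricted and the tree pruned to the clade; columns that are
    all-gap within the clade get grade 0.  Fewer than 3 members is refused:
    rate inference on one or two sequences is unreliable.
    """
    members = sorted(set(clade_members))
    if len(members) < 3:
        raise ValueError("clade profile needs at least 3 members")
    missing = set(members) - set(alignment.ids)
    if missing:
        raise KeyError(f"clade members not in alignment: {sorted(missing)}")
    sub_aln = alignment.subset(members)
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    if set(members) == leaves:
        sub_tree = tree
    else:
        sub_tree = prune_to_taxa(tree, members)
    rates = site_rate_posteriors(sub_aln, sub_tree, model, n_cat=n_cat)
    return profile_from_rates(rates, _occupancy(sub_aln))


def profile_table(
    profile: ConservationProfile,
    alignment: Alignment | None = None,
    ref_id: str | None = None,
):
    """Tidy per-column table (column, ref position/residue, rate, score,
    grade, low-confidence flag)."""
    import pandas as pd

    n = len(profile)
    ref_pos = [None] * n
    ref_res = [None] * n
    if alignment is not None and ref_id is not None:
        from .curation import column_to_reference

        col2ref = column_to_reference(alignment, ref_id)
        row = alignment[ref_id].residues
        for col in range(1, n + 1):
            if col in col2ref:
                ref_pos[col - 1] = col2ref[col]
                ref_res[col - 1] = row[col - 1]
    return pd.DataFrame(
        {
            "column": np.arange(1, n + 1),
            "ref_position": ref_pos,
            "ref_residue": ref_res,
            "rate": profile.posterior_mean_rate,
            "score": profile.normalized_score,
            "grade": profile.grade,
            "low_confidence": profile.low_confidence,
        }
    )
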