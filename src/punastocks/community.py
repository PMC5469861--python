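"""Community composition metrics, indicator-species analysis and trait syndromes.

The community table is a plots x species percent-cover DataFrame, with a
per-plot habitat label Series and a per-species attribute DataFrame
(described/undescribed, native/introduced, latitudinal range in minutes,
binary/ordinal disturbance traits).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .errors import DomainError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# indicator value (IndVal) analysis
# ---------------------------------------------------------------------------

def _indval_matrix(cover: np.ndarray, group_codes: np.ndarray,
                   n_groups: int, presence: bool) -> np.ndarray:
    """IndVal_ij = 100 * A_ij * B_ij for species j in group i.

    A (specificity): mean abundance of the species in group i relative to
    the sum of its group mean abundances.  B (fidelity): fraction of the
    group's plots where the species is present (cover > 0).
    """
    abund = (cover > 0).astype(float) if presence else cover
    means = np.empty((n_groups, cover.shape[1]))
    pres = np.empty_like(means)
    for g in range(n_groups):
        sel = group_codes == g
        means[g] = abund[sel].mean(axis=0)
        pres[g] = (cover[sel] > 0).mean(axis=0)
    colsum = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(colsum > 0, means / colsum, 0.0)
    return 100.0 * a * pres


def indval(cover: pd.DataFrame, groups: pd.Series, n_perm: int = 999,
           seed: int | None = None, exact: bool = False,
           abundance: str = "cover") -> pd.DataFrame:
    """Dufrene-Legendre indicator-species analysis with a permutation null.

    For each species the statistic is the maximum over groups of
    100 * specificity * fidelity.  Significance is assessed by randomly
    reassigning plot group labels: p = (1 + #{permuted max >= observed})
    / (n_perm + 1).  With ``exact=True`` every distinct label ordering is
    enumerated instead (feasible only for tiny tables) and
    p = #{orderings with max >= observed} / #orderings, the identity
    ordering included.

    Parameters
    ----------
    cover
        plots x species percent covers.
    groups
        group label per plot (>= 2 non-empty groups).
    abundance
        "cover" uses the cover values for specificity; "presence" uses
        presence/absence.
    """
    if abundance not in ("cover", "presence"):
        raise ValueError(f"unknown abundance {abundance!r}")
    groups = groups.loc[cover.index]
    codes, uniques = pd.factorize(groups, sort=True)
    n_groups = len(uniques)
    if n_groups < 2:
        raise DomainError("need at least 2 groups")
    if np.bincount(codes, minlength=n_groups).min() == 0:
        raise DomainError("every group must contain at least one plot")
    x = cover.to_numpy(dtype=float)
    present = x.sum(axis=0) > 0
    n_absent = int((~present).sum())
    if n_absent:
        warnings.warn(f"{n_absent} species absent from every plot excluded",
                      stacklevel=2)
    species = cover.columns[present]
    x = x[:, present]
    presence = abundance == "presence"

    stat = _indval_matrix(x, codes, n_groups, presence)
    obs = stat.max(axis=0)
    best = uniques[stat.argmax(axis=0)]

    if exact:
        from sympy.utilities.iterables import multiset_permutations
        count = np.zeros(x.shape[1])
        n_orderings = 0
        for perm in multiset_permutations(list(codes)):
            pm = _indval_matrix(x, np.asarray(perm), n_groups, presence).max(axis=0)
            count += pm >= obs - 1e-12
            n_orderings += 1
        p = count / n_orderings
    else:
        if n_perm < 1:
            raise DomainError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        count = np.zeros(x.shape[1])
        for _ in range(n_perm):
            pm = _indval_matrix(x, rng.permutation(codes), n_groups,
                                presence).max(axis=0)
            count += pm >= obs - 1e-12
        p = (1.0 + count) / (n_perm + 1.0)

    return pd.DataFrame({"species": species, "best_group": best,
                         "indval": obs, "p_value": p}).set_index("species")


# ---------------------------------------------------------------------------
# per-plot composition metrics
# ---------------------------------------------------------------------------

def plot_metrics(cover: pd.DataFrame, attributes: pd.DataFrame) -> pd.DataFrame:
    """Richness, undescribed/introduced cover and proportion, and mean
    latitudinal amplitude of native species, per plot.

    Proportions are relative to the plot's species count; the latitudinal
    amplitude (difference between northern- and southern-most records, in
    latitudinal minutes) is averaged over the native (non-introduced)
    species present, and is NaN for a plot with none.
    """
    missing = [s for s in cover.columns if s not in attributes.index]
    if missing:
        raise DomainError(f"species missing attributes: {missing}")
    attr = attributes.loc[cover.columns]
    undescribed = (attr["status"] == "undescribed").to_numpy()
    introduced = (attr["origin"] == "introduced").to_numpy()
    lat = attr["latitudinal_range_min"].to_numpy(dtype=float)

    x = cover.to_numpy(dtype=float)
    present = x > 0
    richness = present.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        und_prop = np.where(richness > 0,
                            (present & undescribed).sum(axis=1) / richness, 0.0)
        intr_prop = np.where(richness > 0,
                             (present & introduced).sum(axis=1) / richness, 0.0)
    native_present = present & ~introduced
    lat_sum = np.where(native_present, lat, 0.0).sum(axis=1)
    n_native = native_present.sum(axis=1)
    amplitude = np.divide(lat_sum, n_native,
                          out=np.full(len(cover), np.nan), where=n_native > 0)
    return pd.DataFrame({
        "richness": richness,
        "undescribed_cover": (x * undescribed).sum(axis=1),
        "undescribed_proportion": und_prop,
        "introduced_cover": (x * introduced).sum(axis=1),
        "introduced_proportion": intr_prop,
        "mean_latitudinal_amplitude_min": amplitude,
    }, index=cover.index)


# ---------------------------------------------------------------------------
# trait-syndrome scoring (PCA)
# ---------------------------------------------------------------------------

def trait_syndromes(attributes: pd.DataFrame, cover: pd.DataFrame,
                    n_components: int = 8, trait_prefix: str = "trait_",
                    weighted: bool = False) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Score disturbance-trait syndromes per plot via species-level PCA.

    Traits are standardised to zero mean / unit variance, principal
    components extracted, and each component's sign fixed so its
    largest-magnitude loading is positive.  A plot's score on a
    component is the unweighted mean over the species present (the
    default); ``weighted=True`` weights species by their cover instead.
    Constant trait columns are dropped with a warning.

    Returns (per-plot scores, per-species scores, explained variance ratio).
    """
    trait_cols = [c for c in attributes.columns if c.startswith(trait_prefix)]
    if not trait_cols:
        raise DomainError(f"no trait columns with prefix {trait_prefix!r}")
    traits = attributes.loc[cover.columns, trait_cols].astype(float)
    if traits.isna().any().any():
        raise DomainError("trait matrix has missing values")
    constant = traits.columns[traits.nunique() <= 1]
    if len(constant):
        warnings.warn(f"dropping constant trait column(s): {list(constant)}",
                      stacklevel=2)
        traits = traits.drop(columns=constant)
    if n_components > traits.shape[1]:
        raise DomainError("n_components exceeds the number of usable traits")

    z = StandardScaler().fit_transform(traits.to_numpy())
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(z)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(n_components):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            pca.components_[k] *= -1
            scores[:, k] *= -1
    cols = [f"pc{k + 1}" for k in range(n_components)]
    species_scores = pd.DataFrame(scores, index=cover.columns, columns=cols)

    x = cover.to_numpy(dtype=float)
    w = x if weighted else (x > 0).astype(float)
    wsum = w.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        plot_scores = np.where(wsum > 0, (w @ scores) / wsum, np.nan)
    plot_df = pd.DataFrame(plot_scores, index=cover.index, columns=cols)
    return plot_df, species_scores, pca.explained_variance_ratio_
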