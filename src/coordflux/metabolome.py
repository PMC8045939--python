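"""Metabolomics processing: accurate-mass annotation of deprotonated ions,
wild-type-normalized fold changes, variability filtering, K-means clustering
and absolute-concentration conversion."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .physiology import OD_TO_CDW, CELLVOL_PER_CDW

PROTON_MASS = 1.007276  # Da; M−H⁺ deprotonation
DEFAULT_MASS_TOLERANCE = 0.001  # Da
DEFAULT_CV_THRESHOLD = 0.30


class MetabolomeError(ValueError):
    pass


@dataclass
class ClusterResult:
    """K-means partition of retained ions plus the low-variance cluster k+1."""

    labels: pd.Series          # ion → cluster index in 1..k+1
    centroids: np.ndarray      # k × n_conditions, log₂ fold-change space
    k: int
    seed: int
    inertia: float

    @property
    def filtered_cluster(self) -> int:
        return self.k + 1


def annotate_ions(
    mz_values,
    reference_masses: dict[str, float],
    tolerance: float = DEFAULT_MASS_TOLERANCE,
) -> pd.DataFrame:
    """Match observed m/z to neutral monoisotopic masses as [M−H]⁻ ions.

    Expected m/z = neutral mass − 1.007276 Da. Every reference within the
    (boundary-inclusive) tolerance is reported; multiple matches for one ion
    are flagged ambiguous.
    """
    if not reference_masses:
        raise MetabolomeError("empty reference mass list")
    rows = []
    for mz in np.atleast_1d(np.asarray(mz_values, dtype=float)):
        matches = []
        for mid, mass in reference_masses.items():
            expected = mass - PROTON_MASS
            err = mz - expected
            if abs(err) <= tolerance + 1e-12:  # boundary inclusive under float roundoff
                matches.append((mid, err))
        for mid, err in matches:
            rows.append(
                {"mz": float(mz), "metabolite_id": mid, "mass_error_da": float(err),
                 "ambiguous": len(matches) > 1}
            )
        if not matches:
            rows.append(
                {"mz": float(mz), "metabolite_id": None, "mass_error_da": np.nan,
                 "ambiguous": False}
            )
    return pd.DataFrame(rows)


def fold_change_matrix(
    intensities: pd.DataFrame, reference_condition: str
) -> pd.DataFrame:
    """log₂ fold changes of replicate-mean intensities relative to wild type.

    ``intensities``: tidy frame with columns ion_id, condition_id, replicate,
    intensity. Ions with any non-positive mean intensity are excluded.
    """
    means = intensities.pivot_table(
        index="ion_id", columns="condition_id", values="intensity", aggfunc="mean"
    )
    if reference_condition not in means.columns:
        raise MetabolomeError(f"reference condition {reference_condition!r} absent")
    ok = (means > 0).all(axis=1)
    means = means.loc[ok]
    return np.log2(means.divide(means[reference_condition], axis=0))


def cv_filter(
    relative_concentrations: pd.DataFrame,
    threshold: float = DEFAULT_CV_THRESHOLD,
) -> tuple[pd.Index, pd.Index]:
    """Split ions by coefficient of variation across condition means.

    CV = sample sd / mean on the linear scale; ions with CV < threshold go to
    the filtered (low-variance) set. Returns (retained, filtered) indexes.
    """
    if relative_concentrations.shape[1] < 2:
        raise MetabolomeError("need at least 2 conditions")
    mean = relative_concentrations.mean(axis=1)
    if (mean == 0).any():
        raise MetabolomeError("zero mean relative concentration")
    cv = relative_concentrations.std(axis=1, ddof=1) / mean
    filtered = relative_concentrations.index[cv < threshold]
    retained = relative_concentrations.index[cv >= threshold]
    return retained, filtered


def kmeans_cluster(
    fold_changes: pd.DataFrame,
    k: int = 11,
    seed: int = 0,
    restarts: int = 10,
    filtered_ions: pd.Index | None = None,
) -> ClusterResult:
    """Lloyd's K-means (squared Euclidean, k-means++ seeding, best of
    ``restarts`` runs) on retained ions; filtered ions become cluster k+1."""
    n = len(fold_changes)
    if k < 1 or k > n:
        raise MetabolomeError(f"k={k} incompatible with {n} retained ions")
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts,
                random_state=seed)
    raw = km.fit_predict(fold_changes.values)
    labels = pd.Series(raw + 1, index=fold_changes.index, name="cluster")
    if filtered_ions is not None and len(filtered_ions):
        labels = pd.concat(
            [labels, pd.Series(k + 1, index=filtered_ions, name="cluster")]
        )
    return ClusterResult(
        labels=labels, centroids=km.cluster_centers_, k=k, seed=seed,
        inertia=float(km.inertia_),
    )


def absolute_concentration(
    amount_nmol: float, od: float, sample_volume_ml: float
) -> float:
    """Intracellular concentration (mM) from a measured amount.

    Cell volume = OD · 0.413 mg CDW·ml⁻¹·OD⁻¹ · volume · 2.7 µl·mg⁻¹;
    nmol/µl ≡ mM.
    """
    if od <= 0 or sample_volume_ml <= 0:
        raise MetabolomeError("OD and sample volume must be positive")
    if amount_nmol < 0:
        raise MetabolomeError("amount must be >= 0")
    cell_volume_ul = od * OD_TO_CDW * sample_volume_ml * CELLVOL_PER_CDW
    return amount_nmol / cell_volume_ul
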