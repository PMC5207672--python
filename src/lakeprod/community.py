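"""Community-level multivariate analyses.

Two unrelated but equally simple analyses live here:

* Ward minimal-variance hierarchical clustering (and PCA) of lake-water
  ionic composition — seven variables per sample: Na+, K+, Mg2+, Ca2+,
  SO4(2-), Cl- in mg L-1 and total alkalinity in mg L-1 eq CO3(2-).
  Clustering uses the raw concentrations by default because the grouping of
  saline waters is driven by absolute Na+/Cl- levels, which standardisation
  would erase.
* Biolog EcoPlate community-level physiological profiling: blank-corrected
  average well colour development (AWCD) across the 31 carbon substrates,
  and substrate utilisation aggregated into six chemical classes (amines,
  amino acids, carbohydrates, carboxylic acids, phenolic compounds,
  polymers) as percentages of the plate total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .constants import DEFAULT_AWCD_TIME_H

__all__ = [
    "ION_VARIABLES",
    "WaterSample",
    "WardClustering",
    "ward_cluster",
    "composition_pca",
    "EcoplatePlate",
    "ecoplate_class_map",
    "awcd",
    "class_utilization",
]

ION_VARIABLES = ("na", "k", "mg", "ca", "so4", "cl", "tal")

ECOPLATE_CLASSES = ("amines", "amino acids", "carbohydrates",
                    "carboxylic acids", "phenolic compounds", "polymers")

#: label of the substrate-free control well
BLANK_SUBSTRATE = "water"


@dataclass(frozen=True)
class WaterSample:
    """One lake's ionic composition (mg L-1; tal in mg L-1 eq CO3^2-)."""

    label: str
    na: float
    k: float
    mg: float
    ca: float
    so4: float
    cl: float
    tal: float

    def __post_init__(self):
        for name in ION_VARIABLES:
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise ValueError(f"sample {self.label!r}: missing value for {name}")
            if v < 0:
                raise ValueError(f"sample {self.label!r}: negative {name}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in ION_VARIABLES], dtype=float)


def _sample_matrix(samples) -> tuple[np.ndarray, list[str]]:
    if isinstance(samples, pd.DataFrame):
        missing = set(ION_VARIABLES) - set(samples.columns)
        if missing:
            raise ValueError(f"missing ion columns: {sorted(missing)}")
        x = samples[list(ION_VARIABLES)].to_numpy(dtype=float)
        labels = [str(i) for i in samples.index]
    else:
        samples = list(samples)
        x = np.array([s.as_array() for s in samples])
        labels = [s.label for s in samples]
    if np.any(np.isnan(x)):
        raise ValueError("missing values in the chemistry matrix (no imputation)")
    return x, labels


@dataclass
class WardClustering:
    """A Ward dendrogram over water samples, with flat-cut helpers."""

    linkage: np.ndarray
    labels: list[str]
    standardized: bool = False

    def cut(self, n_clusters: int) -> np.ndarray:
        """Integer cluster assignments (1..k) for a flat cut at ``n_clusters``."""
        if len(self.labels) == 1:
            return np.array([1])
        return hierarchy.fcluster(self.linkage, t=n_clusters,
                                  criterion="maxclust")

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2] if len(self.linkage) else np.array([])

    def to_newick(self) -> str:
        """Nested-parenthesis text export of the dendrogram with heights."""
        if len(self.labels) == 1:
            return f"{self.labels[0]};"
        tree = hierarchy.to_tree(self.linkage)

        def rec(node):
            if node.is_leaf():
                return self.labels[node.id]
            left, right = rec(node.left), rec(node.right)
            return f"({left},{right}):{node.dist:.6g}"

        return rec(tree) + ";"


def ward_cluster(samples, standardize: bool = False) -> WardClustering:
    """Ward minimal-variance clustering of ionic compositions.

    Euclidean distances on the raw mg L-1 values (``standardize=True``
    switches to z-scored variables). Missing values raise; they are not
    imputed.
    """
    x, labels = _sample_matrix(samples)
    if len(labels) < 1:
        raise ValueError("need at least one sample")
    if len(labels) == 1:
        return WardClustering(linkage=np.empty((0, 4)), labels=labels,
                              standardized=standardize)
    if standardize:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    z = hierarchy.linkage(x, method="ward", metric="euclidean")
    return WardClustering(linkage=z, labels=labels, standardized=standardize)


def composition_pca(samples, standardize: bool = True) -> dict:
    """PCA of the 7-variable chemistry matrix.

    Defaults to the correlation-matrix form (variables z-scored); constant
    variables are dropped with a warning. Returns scores, loadings (columns
    = retained variables), explained-variance fractions and the variable
    names kept.
    """
    x, labels = _sample_matrix(samples)
    if len(labels) < 3:
        raise ValueError("need at least 3 samples for a PCA")
    keep = [i for i in range(x.shape[1]) if x[:, i].std() > 0]
    dropped = [ION_VARIABLES[i] for i in range(x.shape[1]) if i not in keep]
    if dropped:
        warnings.warn(f"dropping constant variables: {dropped}", UserWarning,
                      stacklevel=2)
    x = x[:, keep]
    names = [ION_VARIABLES[i] for i in keep]
    if standardize:
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    else:
        x = x - x.mean(axis=0)
    pca = PCA()
    scores = pca.fit_transform(x)
    return {
        "scores": pd.DataFrame(scores, index=labels,
                               columns=[f"PC{i+1}" for i in range(scores.shape[1])]),
        "loadings": pd.DataFrame(pca.components_,
                                 index=[f"PC{i+1}" for i in range(scores.shape[1])],
                                 columns=names),
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "variables": names,
    }


def ecoplate_class_map() -> pd.Series:
    """The canonical 31-substrate -> 6-class EcoPlate map (user-overridable).

    Shipped as a data file; counts are 2 amines, 6 amino acids,
    9 carbohydrates, 8 carboxylic acids, 2 phenolic compounds, 4 polymers.
    """
    with resources.files("lakeprod.data").joinpath(
            "ecoplate_classes.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("substrate")["chemical_class"]


@dataclass
class EcoplatePlate:
    """OD-590 kinetics of one EcoPlate (replicate, substrate, time, od).

    ``readings`` has columns replicate, substrate, time_h, od590, including
    blank wells under the substrate label ``"water"``. ``class_map``
    defaults to the shipped canonical map.
    """

    readings: pd.DataFrame
    class_map: pd.Series = field(default_factory=ecoplate_class_map)

    def __post_init__(self):
        need = {"replicate", "substrate", "time_h", "od590"}
        missing = need - set(self.readings.columns)
        if missing:
            raise ValueError(f"readings missing columns: {sorted(missing)}")
        if (self.readings["od590"] < 0).any():
            raise ValueError("optical densities must be non-negative")
        subs = set(self.readings["substrate"]) - {BLANK_SUBSTRATE}
        expected = set(self.class_map.index)
        if subs != expected:
            raise ValueError(
                "plate substrates do not match the 31-substrate class map; "
                f"unexpected: {sorted(subs - expected)}, "
                f"missing: {sorted(expected - subs)}")
        if len(self.class_map) != 31:
            raise ValueError("class map must cover exactly 31 substrates")

    def corrected_od(self, time_h: float = DEFAULT_AWCD_TIME_H) -> pd.DataFrame:
        """Blank-corrected OD per (replicate, substrate) at ``time_h``.

        Negative corrected values are clamped to zero (a well cannot develop
        less colour than the substrate-free control, up to noise).
        """
        at_t = self.readings[self.readings["time_h"] == time_h]
        if at_t.empty:
            raise ValueError(f"no readings at time {time_h} h")
        blanks = (at_t[at_t["substrate"] == BLANK_SUBSTRATE]
                  .groupby("replicate")["od590"].mean())
        if blanks.empty:
            raise ValueError("plate has no blank (water) wells")
        wells = at_t[at_t["substrate"] != BLANK_SUBSTRATE].copy()
        wells["corrected"] = (
            wells["od590"] - wells["replicate"].map(blanks).to_numpy()
        ).clip(lower=0.0)
        return wells


def awcd(plate: EcoplatePlate, time_h: float = DEFAULT_AWCD_TIME_H) -> pd.Series:
    """Average well colour development per replicate at ``time_h``.

    Mean blank-corrected OD over the 31 substrate wells.
    """
    wells = plate.corrected_od(time_h)
    return wells.groupby("replicate")["corrected"].mean()


def class_utilization(plate: EcoplatePlate,
                      time_h: float = DEFAULT_AWCD_TIME_H) -> pd.Series:
    """Substrate utilisation by chemical class, % of the plate total.

    Corrected ODs are averaged over replicates per substrate, summed within
    each of the six classes and expressed relative to the sum over all 31
    substrates. The percentages sum to 100.
    """
    wells = plate.corrected_od(time_h)
    per_substrate = wells.groupby("substrate")["corrected"].mean()
    total = per_substrate.sum()
    if total <= 0:
        raise ValueError("plate shows no colour development at this time")
    by_class = per_substrate.groupby(plate.class_map).sum()
    out = (100.0 * by_class / total).reindex(ECOPLATE_CLASSES, fill_value=0.0)
    out.name = "percent"
    return out
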