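"""Reference-based sorting of single-map reconstructions.

Each single-tube map is compared with two reference maps — one averaged
from ligand-exposed tubes, Ref(+ACh), and one from unexposed tubes,
Ref(-ACh) — and classified by the sign of the correlation difference
``delta = cc_plus - cc_minus``.  Discrimination is sharpened by lowpass
filtering to a resolution limit (default 20 A) and confining the
comparison to the central two-thirds of the molecule along the pore axis,
where the conformational difference is concentrated.  Maps whose |delta|
falls below a weak-preference band are left unassigned ("none"), mirroring
tubes that plausibly contain comparable numbers of open and closed
channels.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .maps import DensityMap, Mask, average, central_mask, correlation, lowpass, section_correlations
from .phantom import MapEnsemble

#: default delta histogram bin width, matched to the phantom delta scale
HIST_BIN_WIDTH = 0.0005


@dataclasses.dataclass
class SortConfig:
    """Settings of the correlation-sorting procedure."""

    resolution_limit: float = 20.0
    central_fraction: float = 2.0 / 3.0
    weak_band: float | None = None    # None: estimated from the delta histogram
    use_sections: bool = False        # score on per-section mean cc instead of 3D cc
    hist_bin_width: float = HIST_BIN_WIDTH

    def __post_init__(self) -> None:
        if self.resolution_limit <= 0:
            raise ValueError("resolution_limit must be positive")
        if not 0 < self.central_fraction <= 1:
            raise ValueError("central_fraction must lie in (0, 1]")
        if self.weak_band is not None and self.weak_band < 0:
            raise ValueError("weak_band must be >= 0")


@dataclasses.dataclass
class ReferenceMaps:
    """The pair (Ref(+ACh), Ref(-ACh)), kept with preprocessed copies."""

    plus: DensityMap
    minus: DensityMap
    plus_filtered: DensityMap | None = None
    minus_filtered: DensityMap | None = None
    mask: Mask | None = None

    def prepared(self, config: SortConfig) -> "ReferenceMaps":
        refs = ReferenceMaps(self.plus, self.minus)
        refs.plus_filtered = lowpass(self.plus, config.resolution_limit)
        refs.minus_filtered = lowpass(self.minus, config.resolution_limit)
        refs.mask = central_mask(self.plus, config.central_fraction)
        return refs


@dataclasses.dataclass
class ClassificationResult:
    """Per-map scores and assignments plus the delta histogram."""

    records: pd.DataFrame              # id, cc_plus, cc_minus, delta, label
    weak_band: float
    weak_fraction: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray

    def counts(self) -> dict[str, int]:
        return self.records["label"].value_counts().to_dict()


def build_references(
    plus_maps: Sequence[DensityMap], minus_maps: Sequence[DensityMap]
) -> ReferenceMaps:
    """Average ligand-exposed and unexposed single-image maps into the
    reference pair."""
    if not plus_maps or not minus_maps:
        raise ValueError("both reference lists must be non-empty")
    return ReferenceMaps(plus=average(plus_maps), minus=average(minus_maps))


def score_map(
    dmap: DensityMap, refs: ReferenceMaps, config: SortConfig | None = None
) -> tuple[float, float, float]:
    """Correlations of one map against both references.

    The map and the references are lowpassed to ``resolution_limit`` and
    compared inside the central-fraction mask.  Returns
    ``(cc_plus, cc_minus, delta)`` with ``delta = cc_plus - cc_minus``.
    """
    config = config or SortConfig()
    if refs.plus_filtered is None or refs.mask is None:
        refs = refs.prepared(config)
    filtered = lowpass(dmap, config.resolution_limit)
    if config.use_sections:
        cc_p = float(np.nanmean(section_correlations(filtered, refs.plus_filtered, refs.mask)))
        cc_m = float(np.nanmean(section_correlations(filtered, refs.minus_filtered, refs.mask)))
    else:
        cc_p = correlation(filtered, refs.plus_filtered, refs.mask)
        cc_m = correlation(filtered, refs.minus_filtered, refs.mask)
    return cc_p, cc_m, cc_p - cc_m


def estimate_weak_band(deltas: np.ndarray) -> float:
    """Weak-preference half-width from a bimodal delta sample.

    Taken as one third of the half-distance between the two modes, located
    as the means of the positive and negative delta sub-samples.  Falls
    back to one third of the delta standard deviation if the sample is
    one-sided.
    """
    deltas = np.asarray(deltas, dtype=float)
    pos, neg = deltas[deltas > 0], deltas[deltas < 0]
    if len(pos) == 0 or len(neg) == 0:
        return float(np.std(deltas) / 3.0)
    half_distance = (pos.mean() - neg.mean()) / 2.0
    return float(half_distance / 3.0)


def sort_ensemble(
    ensemble: MapEnsemble | Sequence[DensityMap],
    refs: ReferenceMaps,
    config: SortConfig | None = None,
    ids: Sequence[str] | None = None,
) -> ClassificationResult:
    """Assign every map to open / closed / none by correlation preference.

    ``delta > weak_band`` -> open (closer to Ref(+ACh)); ``delta <
    -weak_band`` -> closed; otherwise none.  The delta histogram uses the
    fixed bin width from the config.
    """
    config = config or SortConfig()
    maps = ensemble.maps if isinstance(ensemble, MapEnsemble) else list(ensemble)
    if ids is None:
        ids = [f"map_{i:04d}" for i in range(len(maps))]
    refs = refs.prepared(config)
    rows = []
    for map_id, dmap in zip(ids, maps):
        cc_p, cc_m, delta = score_map(dmap, refs, config)
        rows.append({"id": map_id, "cc_plus": cc_p, "cc_minus": cc_m, "delta": delta})
    records = pd.DataFrame(rows)

    weak_band = config.weak_band
    if weak_band is None:
        weak_band = estimate_weak_band(records["delta"].to_numpy())
    labels = np.where(
        records["delta"] > weak_band,
        "open",
        np.where(records["delta"] < -weak_band, "closed", "none"),
    )
    records["label"] = labels
    weak_fraction = float(np.mean(labels == "none"))

    deltas = records["delta"].to_numpy()
    bw = config.hist_bin_width
    lo = np.floor(deltas.min() / bw) * bw
    hi = np.ceil(deltas.max() / bw) * bw
    nbins = max(1, int(round((hi - lo) / bw)))
    counts, edges = np.histogram(deltas, bins=nbins, range=(lo, lo + nbins * bw))
    return ClassificationResult(records, float(weak_band), weak_fraction, counts, edges)


def class_average_and_iterate(
    ensemble: MapEnsemble | Sequence[DensityMap],
    result: ClassificationResult,
    config: SortConfig | None = None,
    resort: bool = True,
) -> tuple[dict[str, DensityMap], ClassificationResult, bool]:
    """Average the sorted maps per class and optionally re-sort once.

    Returns the class-average maps, the (possibly re-sorted) result, and a
    convergence flag (True when the single re-sort pass leaves every
    assignment unchanged).  Mirrors a one-pass refinement: the class
    averages become the new references.
    """
    config = config or SortConfig()
    maps = ensemble.maps if isinstance(ensemble, MapEnsemble) else list(ensemble)
    averages: dict[str, DensityMap] = {}
    for label in ("open", "closed"):
        members = [m for m, lab in zip(maps, result.records["label"]) if lab == label]
        if not members:
            raise ValueError(f"class {label!r} is empty after sorting")
        averages[label] = average(members)
    if not resort:
        return averages, result, True
    refs = ReferenceMaps(plus=averages["open"], minus=averages["closed"])
    new_result = sort_ensemble(
        ensemble, refs, dataclasses.replace(config, weak_band=result.weak_band),
        ids=list(result.records["id"]),
    )
    converged = bool((new_result.records["label"] == result.records["label"]).all())
    return averages, new_result, converged
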