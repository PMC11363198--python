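"""Bundle-level summaries: connectivity profiles, correlation, fROI metrics.

A connectivity profile of an fROI over a fixed bundle set is the percentage
of matched streamlines attributed to each bundle -- the same one-ROI
matching rule as sub-bundle extraction, applied bundle by bundle.  Profiles
of one region computed by two pipelines are compared with the Pearson
correlation of their percentage vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .core import BinaryMask, Tractogram
from .errors import EmptyInputError, ParameterError, ValidationError
from .matching import FSuBResult, MatchParams, extract_fsub


@dataclass
class ConnectivityProfile:
    bundle_names: list[str]
    counts: np.ndarray
    percentages: np.ndarray
    weighted_counts: Optional[np.ndarray] = None
    total_zero: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.percentages = np.asarray(self.percentages, dtype=np.float64)
        if not (len(self.bundle_names) == len(self.counts) == len(self.percentages)):
            raise ValidationError("profile field lengths disagree")
        if self.weighted_counts is not None:
            self.weighted_counts = np.asarray(self.weighted_counts, dtype=np.float64)
        total = self.percentages.sum()
        if self.total_zero:
            if total != 0:
                raise ValidationError("total_zero profile must have all-zero percentages")
        elif abs(total - 100.0) > 1e-9:
            raise ValidationError(f"percentages must sum to 100, got {total}")


def connectivity_profile(
    froi: BinaryMask,
    bundles: dict[str, Tractogram],
    params: Optional[MatchParams] = None,
    weighted: bool = False,
) -> ConnectivityProfile:
    """Percentage of fROI-matched streamlines attributed to each named bundle.

    count_b = number of streamlines in bundle b with >= 1 endpoint matching
    the fROI; percentage_b = 100 * count_b / sum(counts).  The weighted
    variant sums streamline weights instead of counting.
    """
    if not bundles:
        raise ParameterError("need at least one bundle")
    if froi.n_set == 0:
        raise EmptyInputError("empty fROI mask")
    params = params or MatchParams()

    names = list(bundles.keys())
    counts = np.zeros(len(names), dtype=np.int64)
    weighted_counts = np.zeros(len(names), dtype=np.float64)
    for i, name in enumerate(names):
        bundle = bundles[name]
        if len(bundle) == 0:
            continue
        res = extract_fsub(bundle, froi, params=params, roi_names=[name])
        counts[i] = len(res.selected)
        if bundle.weights is not None:
            weighted_counts[i] = float(bundle.weights[res.selected].sum())
        else:
            weighted_counts[i] = float(counts[i])

    basis = weighted_counts if weighted else counts.astype(np.float64)
    total = basis.sum()
    if total == 0:
        return ConnectivityProfile(
            bundle_names=names,
            counts=counts,
            percentages=np.zeros(len(names)),
            weighted_counts=weighted_counts,
            total_zero=True,
        )
    return ConnectivityProfile(
        bundle_names=names,
        counts=counts,
        percentages=100.0 * basis / total,
        weighted_counts=weighted_counts,
    )


def profile_correlation(p: ConnectivityProfile, q: ConnectivityProfile) -> float:
    """Pearson correlation between two profiles' percentage vectors."""
    if p.bundle_names != q.bundle_names:
        raise ValidationError(
            "profiles cover different bundle sets: "
            f"{p.bundle_names} vs {q.bundle_names}"
        )
    if len(p.bundle_names) < 3:
        raise ParameterError("profile correlation needs >= 3 bundles")
    for name, prof in (("first", p), ("second", q)):
        if np.ptp(prof.percentages) == 0:
            raise ParameterError(
                f"{name} profile is constant; correlation is undefined"
            )
    r = stats.pearsonr(p.percentages, q.percentages).statistic
    return float(r)


def fsub_summary(
    res: FSuBResult, fsub: Tractogram, froi: BinaryMask
) -> dict:
    """Summary metrics for one extracted sub-bundle.

    Streamline count, summed weight (count when unweighted), fROI volume in
    mm^3, streamline density per mm^3 of fROI, and mean streamline length.
    """
    count = len(fsub)
    summed_weight = (
        float(fsub.weights.sum()) if fsub.weights is not None else float(count)
    )
    froi_volume = froi.volume_mm3
    mean_length = float(fsub.lengths_mm().mean()) if count else 0.0
    return {
        "n_streamlines": count,
        "n_input": res.n_input,
        "summed_weight": summed_weight,
        "froi_volume_mm3": froi_volume,
        "streamlines_per_mm3": count / froi_volume if froi_volume > 0 else 0.0,
        "mean_streamline_length_mm": mean_length,
        "roi_names": list(res.roi_names),
        "params": {
            "search_type": res.params.search_type,
            "search_dist_mm": res.params.search_dist_mm,
            "forward_step_mm": res.params.forward_step_mm,
        },
        "warnings": list(res.warnings),
    }
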