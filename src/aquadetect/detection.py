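"""Detection of reference species in metagenomes from coverage statistics.

A species is called present in a metagenome when the coverage breadth of its
type-strain genome exceeds 50%.  Below that, low breadth may simply reflect
shallow sequencing: under Poisson coverage a genuinely present genome at
mean depth ``d`` is expected to reach a breadth near ``100*(1-exp(-d))``,
while reads cross-mapped from a related species plateau at the core-genome
fraction no matter how deep the metagenome is.  The calibration procedure
mimics shallow sequencing by stepwise subsampling of mapped reads from deep
metagenomes, records (depth, breadth) pairs, fits the saturating curve

    breadth_threshold(d) = a * b**d + c        (a < 0, 0 < b < 1, 0 < c <= 100)

to each genome's series, and keeps the curve with the smallest asymptote
``c`` (the most conservative, core-genome-sized one).  A sub-50%-breadth
result then counts as a detection only if its breadth clears both a floor
and the fitted curve at its observed depth.

The published default curve is ``-255.58 * 0.358**d + 75.27``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, ParameterError
from .mapping import AlignmentRecord, CoverageProfile, ReferenceSet, compute_coverage

#: Constants of the published default breadth-threshold curve.
PUBLISHED_THRESHOLD = {"a": -255.58, "b": 0.358, "c": 75.27}


@dataclass
class SaturationSeries:
    """(subsample fraction, mean depth, breadth %) points for one genome."""

    genome_id: str
    points: list[tuple[float, float, float]]

    def depths(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    def breadths(self) -> np.ndarray:
        return np.array([p[2] for p in self.points])


@dataclass
class ThresholdModel:
    """Exponential breadth-threshold curve ``a * b**depth + c``.

    ``c`` is the asymptote: the breadth a truly present genome approaches at
    high depth (the core-genome fraction for cross-species mapping).
    """

    a: float
    b: float
    c: float
    source: str = "fitted"  # "fitted" | "published"
    fit_rmse: float | None = None

    def __post_init__(self) -> None:
        if not (self.a < 0 and 0 < self.b < 1 and 0 < self.c <= 100):
            raise ParameterError(
                f"invalid threshold model (a={self.a}, b={self.b}, c={self.c}): "
                "need a < 0, 0 < b < 1, 0 < c <= 100"
            )

    @classmethod
    def published(cls) -> "ThresholdModel":
        return cls(source="published", **PUBLISHED_THRESHOLD)

    def threshold(self, mean_depth: float) -> float:
        """Breadth threshold (%) at a given mean depth; may be negative at low depth."""
        if mean_depth < 0:
            raise ParameterError("mean_depth must be >= 0")
        return self.a * self.b ** mean_depth + self.c

    def to_json(self) -> str:
        d = {"a": self.a, "b": self.b, "c": self.c, "source": self.source}
        if self.fit_rmse is not None:
            d["fit_rmse"] = self.fit_rmse
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ThresholdModel":
        d = json.loads(text)
        return cls(
            a=d["a"], b=d["b"], c=d["c"],
            source=d.get("source", "fitted"),
            fit_rmse=d.get("fit_rmse"),
        )


@dataclass
class DetectionCall:
    genome_id: str
    metagenome_id: str
    breadth_pct: float
    mean_depth: float
    threshold_pct: float
    floor_pct: float
    detected: bool
    rule: str  # breadth_gt_50 | curve_pass | curve_fail | floor_fail


def breadth_threshold(model: ThresholdModel, mean_depth: float) -> float:
    return model.threshold(mean_depth)


def subsample_series(
    alignments: list[AlignmentRecord],
    ref: ReferenceSet,
    total_reads: int,
    fractions: tuple[float, ...] = (0.01, 0.02, 0.05, 0.1, 0.2, 0.4, 0.7, 1.0),
    seed: int = 0,
    nested: bool = True,
) -> dict[str, SaturationSeries]:
    """Stepwise-reduce mapped reads and record depth/breadth per genome.

    Subsampling is without replacement and, by default, nested (the reads at
    a smaller fraction are a subset of those at a larger one) so each series
    is monotone by construction.  Set ``nested=False`` for independent draws
    per fraction.
    """
    if not fractions:
        raise ParameterError("fractions must be non-empty")
    fr = list(fractions)
    if fr != sorted(fr) or any(not (0 < f <= 1) for f in fr):
        raise ParameterError("fractions must be sorted and within (0, 1]")
    if not alignments:
        raise ParameterError("no alignments to subsample")

    rng = np.random.default_rng(seed)
    n = len(alignments)
    order = rng.permutation(n)
    series: dict[str, SaturationSeries] = {
        gid: SaturationSeries(gid, []) for gid in ref.genome_ids
    }
    for f in fr:
        m = max(1, int(round(f * n)))
        if nested:
            take = order[:m]
        else:
            take = rng.choice(n, size=m, replace=False)
        sub = [alignments[i] for i in take] if f < 1.0 else list(alignments)
        profiles = compute_coverage(sub, ref, total_reads=max(total_reads, len(sub)))
        for p in profiles:
            series[p.genome_id].points.append((f, p.mean_depth, p.breadth_pct))
    return series


_B_STARTS = (0.2, 0.358, 0.6)


def fit_saturation(series: SaturationSeries, flat_tol: float = 1e-6) -> ThresholdModel:
    """Bounded least-squares fit of ``a*b**d + c`` to a saturation series.

    Multi-start initialization (``c0`` in {max breadth, 75, 95}; ``b0`` in
    {0.2, 0.358, 0.6}; ``a0 = min breadth - c0``); the best converged start
    by residual sum of squares wins.  Degenerate (flat) series and
    non-convergence raise :class:`FitError` with diagnostics.
    """
    d = series.depths()
    y = series.breadths()
    if len(d) < 5:
        raise ParameterError("need at least 5 saturation points")
    if d.min() <= 0 or d.max() / max(d.min(), 1e-300) < 2:
        raise ParameterError("saturation points must span a >= 2-fold depth range")
    if float(y.max() - y.min()) < max(flat_tol, 1e-12):
        raise FitError(
            "degenerate saturation series: breadth is constant",
            details={"genome_id": series.genome_id, "breadth": float(y[0])},
        )

    def resid(theta):
        a, b, c = theta
        return a * b ** d + c - y

    lo = np.array([-1e4, 1e-9, 1e-9])
    hi = np.array([-1e-9, 1 - 1e-9, 100.0])
    best = None
    diagnostics = []
    for c0 in (float(y.max()), 75.0, 95.0):
        c0 = min(max(c0, 1e-6), 100.0)
        for b0 in _B_STARTS:
            a0 = min(float(y.min()) - c0, -1e-6)
            x0 = np.clip([a0, b0, c0], lo, hi)
            try:
                res = least_squares(
                    resid, x0, bounds=(lo, hi),
                    xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000,
                )
            except Exception as exc:  # pragma: no cover - scipy internal failure
                diagnostics.append({"x0": list(x0), "error": str(exc)})
                continue
            if not res.success:
                diagnostics.append({"x0": list(x0), "status": int(res.status)})
                continue
            sse = float(np.sum(res.fun ** 2))
            if best is None or sse < best[0]:
                best = (sse, res.x)
    if best is None:
        raise FitError(
            "saturation fit failed to converge from all starts",
            details={"genome_id": series.genome_id, "starts": diagnostics},
        )
    sse, (a, b, c) = best
    rmse = float(np.sqrt(sse / len(d)))
    return ThresholdModel(a=float(a), b=float(b), c=float(c), source="fitted", fit_rmse=rmse)


def select_min_asymptote(models: dict[str, ThresholdModel] | list[ThresholdModel]) -> ThresholdModel:
    """Pick the model with the smallest asymptote ``c`` (most conservative).

    With a dict keyed by genome id, ties are broken by lexicographic genome
    id; with a plain list, by position.
    """
    if isinstance(models, dict):
        items = sorted(models.items())
    else:
        items = list(enumerate(models))
    if not items:
        raise ParameterError("no models to select from")
    return min(items, key=lambda kv: kv[1].c)[1]


def classify_detection(
    profile: CoverageProfile,
    model: ThresholdModel,
    metagenome_id: str = "",
    breadth_cutoff_pct: float = 50.0,
    floor_pct: float = 10.0,
    min_depth: float | None = None,
) -> DetectionCall:
    """Apply the two-branch detection rule to one coverage profile.

    Detected iff breadth is strictly above ``breadth_cutoff_pct``; otherwise
    iff breadth clears a floor AND strictly exceeds the fitted curve at the
    observed mean depth.  The secondary-branch floor is a breadth floor
    (default 10 percentage points); pass ``min_depth`` to use a minimum
    mean-depth condition instead.
    """
    b, dep = profile.breadth_pct, profile.mean_depth
    thr = model.threshold(dep)
    if b > breadth_cutoff_pct:
        detected, rule = True, "breadth_gt_50"
    else:
        floor_ok = (dep >= min_depth) if min_depth is not None else (b >= floor_pct)
        if not floor_ok:
            detected, rule = False, "floor_fail"
        elif b > thr:
            detected, rule = True, "curve_pass"
        else:
            detected, rule = False, "curve_fail"
    return DetectionCall(
        genome_id=profile.genome_id,
        metagenome_id=metagenome_id,
        breadth_pct=b,
        mean_depth=dep,
        threshold_pct=thr,
        floor_pct=floor_pct,
        detected=detected,
        rule=rule,
    )


def detection_report(
    profiles: list[CoverageProfile],
    model: ThresholdModel,
    metagenome_id: str,
    **classify_kwargs,
):
    """One table row per genome: coverage stats, threshold, verdict.

    Returns a pandas DataFrame with a stable column order, ready for TSV
    serialization.
    """
    import pandas as pd

    rows = []
    for p in profiles:
        call = classify_detection(p, model, metagenome_id=metagenome_id, **classify_kwargs)
        rows.append(
            {
                "metagenome_id": metagenome_id,
                "genome_id": p.genome_id,
                "breadth_pct": p.breadth_pct,
                "mean_depth": p.mean_depth,
                "mapped_reads": p.mapped_reads,
                "mapped_read_pct": p.mapped_read_pct,
                "threshold_pct": call.threshold_pct,
                "detected": call.detected,
                "rule": call.rule,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "metagenome_id", "genome_id", "breadth_pct", "mean_depth",
            "mapped_reads", "mapped_read_pct", "threshold_pct", "detected", "rule",
        ],
    )
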