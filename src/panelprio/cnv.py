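"""Coverage-based CNV calling (gene dose + z-score) and qPCR confirmation.

The caller compares a test sample's relative (median-normalized) target
depths against a reference baseline built from the other samples of the same
batch. Two statistics are computed per target: the *gene dose* — the ratio
of the sample's relative depth to the reference mean, expected near 0.5 for
a heterozygous deletion and 1.5 for a duplication — and the *z-score* of the
relative depth against the reference distribution. A target is called only
when BOTH statistics cross their thresholds; adjacent same-type calls within
one gene are merged into events.

Confirmation arithmetic follows the comparative Ct method: fold change =
2^-ddCt with negative-control calibrator samples as references.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .types import CoverageMatrix, CtRole, CtTable, GenomicInterval


@dataclass
class CnvParams:
    """Calling thresholds; dose bounds and the z floor act conjunctively.

    ``sd_floor`` (relative-depth units) bounds the z denominator away from
    zero on degenerate references; ``max_ref_cv`` and ``min_ref_depth`` mask
    targets whose baseline is too noisy or too shallow to judge.
    """

    z_min: float = 2.5
    dose_del_max: float = 0.7
    dose_dup_min: float = 1.3
    min_targets: int = 1
    max_ref_cv: float = 0.3
    min_ref_depth: float = 0.1
    sd_floor: float = 0.05

    def __post_init__(self) -> None:
        if not (self.dose_del_max < 1.0 < self.dose_dup_min):
            raise ValueError("need dose_del_max < 1 < dose_dup_min")
        if self.z_min <= 0:
            raise ValueError("z_min must be > 0")


class CallState(str, enum.Enum):
    DEL = "DEL"
    DUP = "DUP"
    NEUTRAL = "NEUTRAL"
    MASKED = "MASKED"


@dataclass
class TargetCall:
    target: GenomicInterval
    sample_id: str
    rel_depth: float
    dose: float
    z: float
    state: CallState = CallState.NEUTRAL


@dataclass
class CnvEvent:
    sample_id: str
    gene: str
    span: tuple[GenomicInterval, GenomicInterval]
    n_targets: int
    mean_dose: float
    extreme_z: float
    type: CallState


@dataclass
class ReferenceStats:
    mean: np.ndarray
    sd: np.ndarray
    masked: np.ndarray  # boolean per target


@dataclass
class DdctResult:
    sample_id: str
    assay_id: str
    delta_ct_test: float
    delta_ct_calibrator: float
    ddct: float
    fold_change: float = field(init=False)

    def __post_init__(self) -> None:
        self.fold_change = 2.0 ** (-self.ddct)


def normalize_matrix(m: CoverageMatrix) -> CoverageMatrix:
    """Remove library-size effects: divide each column by its median depth.

    After normalization every sample's median target depth equals 1, so a
    sample sequenced at half the depth of its batch-mates is no longer an
    apparent whole-panel deletion.
    """
    if len(m.samples) < 2:
        raise ValueError("normalization needs >= 2 samples")
    medians = np.median(m.depth, axis=0)
    zero = np.flatnonzero(medians == 0)
    if zero.size:
        raise ValueError(
            f"sample(s) with zero median depth: {[m.samples[i] for i in zero]}"
        )
    return CoverageMatrix(
        targets=m.targets, samples=m.samples, depth=m.depth / medians
    )


def reference_stats(
    m: CoverageMatrix, test_sample: str, params: CnvParams | None = None
) -> ReferenceStats:
    """Per-target mean/sd over all batch samples except the test sample.

    Targets are MASKED when the reference mean is below ``min_ref_depth``
    (too shallow to judge) or the coefficient of variation exceeds
    ``max_ref_cv`` (intrinsically noisy capture).
    """
    params = params or CnvParams()
    idx = m.samples.index(test_sample)
    ref = np.delete(m.depth, idx, axis=1)
    if ref.shape[1] < 3:
        raise ValueError(
            f"need >= 3 reference samples, have {ref.shape[1]}"
        )
    mean = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.inf)
    masked = (mean < params.min_ref_depth) | (cv > params.max_ref_cv)
    return ReferenceStats(mean=mean, sd=sd, masked=masked)


def compute_dose_z(
    m: CoverageMatrix,
    test_sample: str,
    stats: ReferenceStats,
    params: CnvParams | None = None,
) -> list[TargetCall]:
    """Gene dose and z-score per target for one test sample.

    dose = rel_depth / reference mean; z = (rel_depth - mean) / max(sd,
    sd_floor). Masked targets propagate as MASKED and are never called.
    """
    params = params or CnvParams()
    col = m.column(test_sample)
    out: list[TargetCall] = []
    for i, iv in enumerate(m.targets):
        if stats.masked[i]:
            out.append(
                TargetCall(
                    target=iv,
                    sample_id=test_sample,
                    rel_depth=float(col[i]),
                    dose=float("nan"),
                    z=float("nan"),
                    state=CallState.MASKED,
                )
            )
            continue
        mean = stats.mean[i]
        dose = float(col[i] / mean)
        z = float((col[i] - mean) / max(stats.sd[i], params.sd_floor))
        out.append(
            TargetCall(
                target=iv, sample_id=test_sample, rel_depth=float(col[i]),
                dose=dose, z=z,
            )
        )
    return out


def call_targets(
    calls: list[TargetCall], params: CnvParams | None = None
) -> list[TargetCall]:
    """Apply the conjunctive dose/z thresholds to each unmasked target."""
    params = params or CnvParams()
    for c in calls:
        if c.state is CallState.MASKED:
            continue
        if c.dose <= params.dose_del_max and c.z <= -params.z_min:
            c.state = CallState.DEL
        elif c.dose >= params.dose_dup_min and c.z >= params.z_min:
            c.state = CallState.DUP
        else:
            c.state = CallState.NEUTRAL
    return calls


def segment_events(
    calls: list[TargetCall], params: CnvParams | None = None
) -> list[CnvEvent]:
    """Merge maximal runs of same-type calls within one gene into events.

    Calls must be ordered by genomic position. A NEUTRAL or MASKED target
    breaks a run (no bridging); events spanning fewer than ``min_targets``
    targets are dropped.
    """
    params = params or CnvParams()
    events: list[CnvEvent] = []
    run: list[TargetCall] = []

    def flush() -> None:
        if len(run) >= params.min_targets:
            doses = [c.dose for c in run]
            zs = [c.z for c in run]
            events.append(
                CnvEvent(
                    sample_id=run[0].sample_id,
                    gene=run[0].target.label,
                    span=(run[0].target, run[-1].target),
                    n_targets=len(run),
                    mean_dose=float(np.mean(doses)),
                    extreme_z=float(max(zs, key=abs)),
                    type=run[0].state,
                )
            )
        run.clear()

    for c in calls:
        if c.state in (CallState.DEL, CallState.DUP):
            if run and (
                c.state is not run[0].state or c.target.label != run[0].target.label
            ):
                flush()
            run.append(c)
        else:
            flush()
    flush()
    return events


def call_sample(
    m: CoverageMatrix, test_sample: str, params: CnvParams | None = None
) -> list[CnvEvent]:
    """Convenience pipeline: normalize, baseline, dose/z, call, segment."""
    params = params or CnvParams()
    norm = normalize_matrix(m)
    stats = reference_stats(norm, test_sample, params)
    calls = compute_dose_z(norm, test_sample, stats, params)
    return segment_events(call_targets(calls, params), params)


def ddct_fold_change(table: CtTable) -> list[DdctResult]:
    """Comparative Ct relative quantification per test sample and assay.

    Replicate Cts are averaged arithmetically. Per sample,
    dCt = mean Ct(target assay) - mean Ct(reference assay); ddCt subtracts
    the mean dCt of the calibrator (negative-control) samples; fold change
    is 2^-ddCt — near 0.5 for a heterozygous deletion, near 2 for a
    duplication, 1 for neutral copy number.
    """
    # mean Ct per (sample, assay role) over replicates; keep assay id of TARGET
    sums: dict[tuple[str, CtRole, str], list[float]] = {}
    calibrators: set[str] = set()
    target_assay: dict[str, str] = {}
    for r in table.rows:
        sums.setdefault((r.sample_id, r.role, r.assay_id), []).append(r.ct)
        if r.calibrator:
            calibrators.add(r.sample_id)
        if r.role is CtRole.TARGET:
            target_assay[r.sample_id] = r.assay_id

    def mean_ct(sample: str, role: CtRole) -> float:
        cts = [
            v
            for (s, ro, _a), vals in sums.items()
            if s == sample and ro is role
            for v in vals
        ]
        if not cts:
            raise ValueError(f"sample {sample!r} lacks a {role.value} assay")
        return float(np.mean(cts))

    samples = sorted({s for s, _, _ in sums})
    dct = {s: mean_ct(s, CtRole.TARGET) - mean_ct(s, CtRole.REFERENCE) for s in samples}
    if not calibrators:
        raise ValueError("no calibrator samples in Ct table")
    cal_dct = float(np.mean([dct[s] for s in sorted(calibrators)]))

    results: list[DdctResult] = []
    for s in samples:
        if s in calibrators:
            continue
        results.append(
            DdctResult(
                sample_id=s,
                assay_id=target_assay.get(s, ""),
                delta_ct_test=dct[s],
                delta_ct_calibrator=cal_dct,
                ddct=dct[s] - cal_dct,
            )
        )
    return results
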