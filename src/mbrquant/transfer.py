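"""Match-between-runs: donor selection, region location, transfer and scoring.

Donor/acceptor run pairs are ranked by a combined correlation
(o*r1 + o*r2)/2 (or /3 with ion mobility), where o is the overlap ratio of
the two runs' identified ion sets and r1/r2/r3 are Spearman rank
correlations of retention time, intensity and ion mobility over shared
ions.  For a donor ion with retention time t, the acceptor-side target
region is [d_i + m - 2*sigma, d_i + m + 2*sigma] where d_i anchors t in the
sorted shared-ion RT pairing, and m/sigma are the median and median
absolute deviation of acceptor-minus-donor RT offsets within a tau window
around d_i.  Decoy transfers repeat the trace at m/z shifted by
+k*1.0005 Th, k = 11 down to 4.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.stats import spearmanr

from .model import DEFAULT_LAMBDA_COEF, IonKey, PROTON_MASS, RunPeakMap, TracedFeature
from .tracing import TraceParams, quantify_feature

DECOY_SPACING = 1.0005
DECOY_SHIFTS = tuple(range(11, 3, -1))  # k = 11, 10, ..., 4


@dataclasses.dataclass
class IonObservation:
    """Per-run summary of one identified ion (for pairing and correlation)."""

    rt: float
    intensity: float
    calibrated_mz: float
    protein_ids: tuple[str, ...]
    im: float | None = None


@dataclasses.dataclass
class RunPairCorrelation:
    donor_id: str
    acceptor_id: str
    o: float
    r1: float
    r2: float
    r3: float | None
    combined: float


def compute_pair_correlation(
    donor: dict[IonKey, IonObservation],
    acceptor: dict[IonKey, IonObservation],
    donor_id: str = "donor",
    acceptor_id: str = "acceptor",
) -> RunPairCorrelation:
    """Overlap-weighted Spearman correlation between two runs' ion summaries.

    o = |shared| / min(|donor|, |acceptor|).  With fewer than three shared
    ions the combined correlation is 0.  Symmetric in the two runs.
    """
    shared = sorted(set(donor) & set(acceptor))
    denom = min(len(donor), len(acceptor))
    o = len(shared) / denom if denom else 0.0
    if len(shared) < 3:
        return RunPairCorrelation(donor_id, acceptor_id, o, 0.0, 0.0, None, 0.0)

    d_rt = np.array([donor[k].rt for k in shared])
    a_rt = np.array([acceptor[k].rt for k in shared])
    d_i = np.array([donor[k].intensity for k in shared])
    a_i = np.array([acceptor[k].intensity for k in shared])

    def _rho(x, y):
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return 0.0
        r = spearmanr(x, y).statistic
        return 0.0 if not np.isfinite(r) else float(r)

    r1 = _rho(d_rt, a_rt)
    r2 = _rho(d_i, a_i)
    have_im = all(donor[k].im is not None and acceptor[k].im is not None
                  for k in shared)
    if have_im:
        r3 = _rho(np.array([donor[k].im for k in shared]),
                  np.array([acceptor[k].im for k in shared]))
        combined = (o * r1 + o * r2 + o * r3) / 3.0
    else:
        r3 = None
        combined = (o * r1 + o * r2) / 2.0
    return RunPairCorrelation(donor_id, acceptor_id, o, r1, r2, r3, combined)


def select_donor_runs(
    acceptor: str,
    correlations: list[RunPairCorrelation],
    top_n: int = 10,
    min_corr: float = 0.0,
) -> list[str]:
    """Up to ``top_n`` donor run ids with combined correlation > ``min_corr``,
    highest first; ties broken lexicographically by run id."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    cands = []
    for c in correlations:
        if c.acceptor_id == acceptor:
            cands.append((c.combined, c.donor_id))
        elif c.donor_id == acceptor:
            cands.append((c.combined, c.acceptor_id))
    cands = [(s, r) for s, r in cands if s > min_corr]
    cands.sort(key=lambda t: (-t[0], t[1]))
    return [r for _, r in cands[:top_n]]


@dataclasses.dataclass
class RtPairing:
    """Sorted (donor, acceptor) coordinate pairs over shared ions."""

    d: np.ndarray
    a: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        order = np.argsort(self.d, kind="stable")
        self.d = self.d[order]
        self.a = self.a[order]

    @property
    def n(self) -> int:
        return int(self.d.size)

    @classmethod
    def build(
        cls,
        donor: dict[IonKey, IonObservation],
        acceptor: dict[IonKey, IonObservation],
        coord: str = "rt",
    ) -> "RtPairing | None":
        shared = sorted(set(donor) & set(acceptor))
        if coord == "im":
            shared = [k for k in shared
                      if donor[k].im is not None and acceptor[k].im is not None]
            if not shared:
                return None
            d = [donor[k].im for k in shared]
            a = [acceptor[k].im for k in shared]
        else:
            if not shared:
                return None
            d = [donor[k].rt for k in shared]
            a = [acceptor[k].rt for k in shared]
        return cls(d=np.array(d), a=np.array(a))


@dataclasses.dataclass
class TransferRegion:
    """An acceptor-side search region: [d_i + m - 2s, d_i + m + 2s]."""

    rt_lo: float
    rt_hi: float
    m: float
    sigma: float
    tau: float

    @property
    def center(self) -> float:
        return 0.5 * (self.rt_lo + self.rt_hi)


def locate_region(pairing: RtPairing, t: float, tau: float) -> TransferRegion:
    """Locate the target range for a donor coordinate ``t``.

    The anchor index i satisfies d_i <= t < d_{i+1} (clamped to the ends);
    pairs with |d_j - d_i| <= tau contribute offsets a_j - d_j whose median
    m and median absolute deviation sigma define the region.
    """
    if pairing is None or pairing.n == 0:
        raise ValueError("empty pairing")
    d, a = pairing.d, pairing.a
    i = int(np.searchsorted(d, t, side="right")) - 1
    i = min(max(i, 0), pairing.n - 1)
    anchor = d[i]
    mask = np.abs(d - anchor) <= tau
    offsets = a[mask] - d[mask]
    m = float(np.median(offsets))
    sigma = float(np.median(np.abs(offsets - m)))
    return TransferRegion(rt_lo=anchor + m - 2 * sigma, rt_hi=anchor + m + 2 * sigma,
                          m=m, sigma=sigma, tau=tau)


def locate_rt_region(pairing: RtPairing, t: float, tau: float = 1.0) -> TransferRegion:
    return locate_region(pairing, t, tau)


def locate_im_region(pairing: RtPairing, im: float, window: float = 0.05) -> TransferRegion:
    return locate_region(pairing, im, window)


def decoy_mz_candidates(target_mz: float) -> list[float]:
    """Decoy m/z positions target + k*1.0005 Th for k = 11 down to 4."""
    if target_mz <= 0:
        raise ValueError("target m/z must be positive")
    return [target_mz + k * DECOY_SPACING for k in DECOY_SHIFTS]


def isotope_kl(
    observed: tuple[float, float, float],
    mono_mz: float,
    charge: int,
    lambda_coef: float = DEFAULT_LAMBDA_COEF,
) -> float:
    """KL divergence (nats) of the observed 0/+1/+2 envelope vs. a truncated
    Poisson model with rate lambda = coef * (mono_mz - 1.00728) * charge.

    Observed intensities are normalized to proportions; zero-probability
    observed terms contribute 0.  All-zero observed input is an error.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.min() < 0:
        raise ValueError("observed isotope intensities must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise ValueError("at least one observed isotope intensity must be positive")
    p = obs / total
    lam = lambda_coef * (mono_mz - PROTON_MASS) * charge
    k = np.arange(3)
    log_pois = k * math.log(lam) - lam - np.array([0.0, 0.0, math.log(2.0)])
    pois = np.exp(log_pois)
    q = pois / pois.sum()
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / q[nz])))


def _signed_sqrt(x: float) -> float:
    return math.copysign(math.sqrt(abs(x)), x)


@dataclasses.dataclass
class TransferScores:
    """Per-transfer quality scores (the b_i of the composite score).

    Square-root transforms of the absolute differences are applied as
    declared; the log10 KL term keeps its sign through a signed square root
    so the score stays monotone in the divergence.
    """

    log_intensity: float
    log_kl: float
    abs_ppm_sqrt: float
    rt_diff_sqrt: float
    im_diff_sqrt: float | None = None

    def vector(self, with_im: bool) -> np.ndarray:
        v = [self.log_intensity, self.log_kl, self.abs_ppm_sqrt, self.rt_diff_sqrt]
        if with_im:
            v.append(0.0 if self.im_diff_sqrt is None else self.im_diff_sqrt)
        return np.asarray(v, dtype=float)


def score_candidate(
    feature: TracedFeature,
    query_mz: float,
    predicted_rt: float,
    predicted_im: float | None = None,
    donor_rt: float | None = None,
    kl_floor: float = 1e-6,
    lambda_coef: float = DEFAULT_LAMBDA_COEF,
    rt_diff_reference: str = "aligned",
) -> TransferScores | None:
    """Compute the per-transfer scores for a traced candidate feature.

    Returns ``None`` for a zero-intensity feature (candidate dropped).  The
    RT difference is measured against the alignment-predicted RT (d_i + m)
    by default, or against the raw donor RT with ``rt_diff_reference="donor"``.
    """
    if feature.intensity <= 0:
        return None
    kl = isotope_kl(feature.isotope_intensities, query_mz, feature.charge,
                    lambda_coef)
    ref_rt = donor_rt if (rt_diff_reference == "donor" and donor_rt is not None) \
        else predicted_rt
    im_diff = None
    if predicted_im is not None and feature.im_center is not None:
        im_diff = math.sqrt(abs(feature.im_center - predicted_im))
    return TransferScores(
        log_intensity=math.log10(feature.intensity),
        log_kl=_signed_sqrt(math.log10(max(kl, kl_floor))),
        abs_ppm_sqrt=math.sqrt(abs(feature.mass_error_ppm)),
        rt_diff_sqrt=math.sqrt(abs(feature.rt_apex - ref_rt)),
        im_diff_sqrt=im_diff,
    )


@dataclasses.dataclass
class TransferCandidate:
    """A donor ion matched into an acceptor region (target or decoy)."""

    ion: IonKey
    donor_run: str
    acceptor_run: str
    ion_type: int  # 1 | -1 | 2 | -2
    feature: TracedFeature
    scores: TransferScores
    protein_ids: tuple[str, ...]
    cv: float | None = None
    composite: float | None = None

    @property
    def is_target(self) -> bool:
        return self.ion_type > 0

    @property
    def leading_protein(self) -> str:
        return self.protein_ids[0] if self.protein_ids else ""


def transfer_ion(
    ion: IonKey,
    obs: IonObservation,
    donor_run: str,
    acceptor_map: RunPeakMap,
    rt_pairing: RtPairing,
    im_pairing: RtPairing | None,
    acceptor_ions: set[IonKey],
    params: TraceParams,
    tau_rt: float = 1.0,
    tau_im: float = 0.05,
    kl_floor: float = 1e-6,
    lambda_coef: float = DEFAULT_LAMBDA_COEF,
    rt_diff_reference: str = "aligned",
    cv: float | None = None,
) -> tuple[TransferCandidate | None, TransferCandidate | None]:
    """Transfer one donor ion into an acceptor run; returns (target, decoy).

    The target region is located from the RT (and IM) pairings; the feature
    is traced at the donor's calibrated m/z.  On success a decoy transfer is
    attempted in the same region over the shifted m/z candidates, stopping
    at the first traceable peak.  Absence of a traced peak yields ``None``.
    """
    region = locate_rt_region(rt_pairing, obs.rt, tau_rt)
    # The region is anchored at the nearest shared-ion RT (d_i); with sparse
    # pairings the donor's own aligned coordinate t + m can fall outside it.
    # Trace a window covering both, with the aligned coordinate as apex hint.
    predicted_rt = obs.rt + region.m
    rt_lo = min(region.rt_lo, predicted_rt - params.min_rt_halfwidth)
    rt_hi = max(region.rt_hi, predicted_rt + params.min_rt_halfwidth)
    im_lo = im_hi = predicted_im = None
    if im_pairing is not None and obs.im is not None:
        im_region = locate_im_region(im_pairing, obs.im, tau_im)
        predicted_im = obs.im + im_region.m
        im_lo = min(im_region.rt_lo, predicted_im - params.min_im_halfwidth)
        im_hi = max(im_region.rt_hi, predicted_im + params.min_im_halfwidth)

    ttype = 2 if ion in acceptor_ions else 1

    def trace_and_score(mz: float, ion_type: int) -> TransferCandidate | None:
        feature = quantify_feature(
            acceptor_map, mz, ion.charge, rt_lo, rt_hi,
            im_lo=im_lo, im_hi=im_hi, apex_hint=predicted_rt, params=params,
        )
        if feature is None:
            return None
        scores = score_candidate(
            feature, mz, predicted_rt, predicted_im, donor_rt=obs.rt,
            kl_floor=kl_floor, lambda_coef=lambda_coef,
            rt_diff_reference=rt_diff_reference,
        )
        if scores is None:
            return None
        return TransferCandidate(
            ion=ion, donor_run=donor_run, acceptor_run=acceptor_map.run_id,
            ion_type=ion_type, feature=feature, scores=scores,
            protein_ids=obs.protein_ids, cv=cv,
        )

    target = trace_and_score(obs.calibrated_mz, ttype)
    decoy = None
    if target is not None:
        for mz_d in decoy_mz_candidates(obs.calibrated_mz):
            decoy = trace_and_score(mz_d, -ttype)
            if decoy is not None:
                break
    return target, decoy


def deduplicate_transfers(
    cands: list[TransferCandidate],
    ppm_tolerance: float = 10.0,
) -> list[TransferCandidate]:
    """Keep one candidate per acceptor feature location.

    Two candidates occupy the same location when they are in the same run,
    their monoisotopic m/z agree within the ppm tolerance and their RT
    bounds overlap.  The highest composite score survives; exact ties go to
    the lexicographically smallest ion key.  Candidates must carry composite
    scores.
    """
    for c in cands:
        if c.composite is None:
            raise ValueError("deduplicate_transfers requires composite scores")
    survivors: list[TransferCandidate] = []
    by_run: dict[tuple[str, float | None], list[TransferCandidate]] = {}
    for c in cands:
        by_run.setdefault((c.acceptor_run, c.cv), []).append(c)
    for _, group in sorted(by_run.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))):
        group.sort(key=lambda c: c.feature.mono_mz)
        # cluster by m/z proximity (chained), then split by RT overlap
        clusters: list[list[TransferCandidate]] = []
        for c in group:
            if clusters and (c.feature.mono_mz - clusters[-1][-1].feature.mono_mz
                             <= c.feature.mono_mz * ppm_tolerance * 1e-6):
                clusters[-1].append(c)
            else:
                clusters.append([c])
        for cluster in clusters:
            cluster.sort(key=lambda c: c.feature.rt_start)
            comp: list[TransferCandidate] = []
            comp_end = -np.inf
            for c in cluster:
                if comp and c.feature.rt_start > comp_end:
                    survivors.append(_best(comp))
                    comp = []
                    comp_end = -np.inf
                comp.append(c)
                comp_end = max(comp_end, c.feature.rt_end)
            if comp:
                survivors.append(_best(comp))
    return survivors


def _best(group: list[TransferCandidate]) -> TransferCandidate:
    return min(group, key=lambda c: (-c.composite, c.ion, c.donor_run))
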