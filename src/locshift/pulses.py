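"""Nuclear-localization pulsing from time-lapse pixel intensities.

Each movie frame of a tracked cell is a sample of pixel intensities.  A
two-component generative model — a Gaussian for the diffuse cytoplasmic GFP
signal plus a uniform for the bright nuclear signal — is fit per frame by
expectation-maximization, deciding simultaneously whether a nucleus is
visible (model selection by BIC plus a minimum mixture weight) and which
pixels belong to it (posterior responsibilities).  The per-frame
localization score is the expected fraction of total intensity attributed
to the nuclear component; pulses are peaks in the score trace and their
durations are peak widths at half prominence, converted to minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, peak_widths
from scipy.stats import norm, t as t_dist

MIN_PIXELS = 20
DEFAULT_W_MIN = 0.02
DEFAULT_MIN_PROMINENCE = 0.1


@dataclass
class FrameObservation:
    """Pixel-intensity sample of one cell in one movie frame."""

    cell_id: str
    frame: int
    pixels: np.ndarray
    frame_interval_min: float = 2.5

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.frame_interval_min <= 0:
            raise ValueError("frame interval must be positive")


@dataclass
class FrameModelFit:
    """Fitted cytoplasm Gaussian + nuclear uniform mixture for one frame."""

    mu_c: float
    sigma_c: float
    w: float                      # nuclear (uniform) mixture weight
    support: tuple[float, float]  # uniform support (a, b), the observed range
    nucleus_visible: bool
    posterior: np.ndarray         # per-pixel P(nuclear | intensity)
    loglik: float
    bic_mixture: float
    bic_gaussian: float


def _mixture_loglik(x, w, mu, sigma, a, b):
    dens = w / (b - a) + (1.0 - w) * norm.pdf(x, mu, sigma)
    return float(np.log(np.maximum(dens, 1e-300)).sum())


def fit_frame_model(
    frame: FrameObservation,
    w_min: float = DEFAULT_W_MIN,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> FrameModelFit:
    """EM fit of ``w*Uniform(a,b) + (1-w)*Normal(mu,sigma)`` to frame pixels.

    The uniform support is fixed to the frame's observed intensity range.
    The nucleus is declared visible when the two-component model is
    preferred by BIC and the fitted weight reaches ``w_min``; otherwise the
    frame is refit as a pure Gaussian with w = 0.
    """
    x = frame.pixels
    if x.size < MIN_PIXELS:
        raise ValueError(f"need at least {MIN_PIXELS} pixels, got {x.size}")
    a, b = float(x.min()), float(x.max())
    if b <= a:
        raise ValueError("degenerate frame: constant pixel intensities")
    n = x.size
    u_dens = 1.0 / (b - a)

    w = 0.1
    mu = float(np.median(x))
    sigma = max(float(1.4826 * np.median(np.abs(x - mu))), 1e-6)
    ll_old = -np.inf
    for _ in range(max_iter):
        nuc = w * u_dens
        cyt = (1.0 - w) * norm.pdf(x, mu, sigma)
        total = np.maximum(nuc + cyt, 1e-300)
        r = nuc / total
        w = float(r.mean())
        wc = (1.0 - r).sum()
        if wc <= 0:
            break
        mu = float(((1.0 - r) * x).sum() / wc)
        sigma = max(float(np.sqrt(((1.0 - r) * (x - mu) ** 2).sum() / wc)), 1e-6)
        ll = _mixture_loglik(x, w, mu, sigma, a, b)
        if ll - ll_old < tol:
            break
        ll_old = ll
    ll_mix = _mixture_loglik(x, w, mu, sigma, a, b)

    mu_g = float(x.mean())
    sigma_g = max(float(x.std()), 1e-6)
    ll_gauss = float(norm.logpdf(x, mu_g, sigma_g).sum())
    # mixture params: w, mu, sigma plus the two data-determined support ends
    bic_mix = 5 * np.log(n) - 2 * ll_mix
    bic_gauss = 2 * np.log(n) - 2 * ll_gauss

    visible = (bic_mix < bic_gauss) and (w >= w_min)
    if not visible:
        return FrameModelFit(
            mu_g, sigma_g, 0.0, (a, b), False, np.zeros(n), ll_gauss, bic_mix, bic_gauss
        )
    nuc = w * u_dens
    cyt = (1.0 - w) * norm.pdf(x, mu, sigma)
    posterior = nuc / np.maximum(nuc + cyt, 1e-300)
    return FrameModelFit(mu, sigma, w, (a, b), True, posterior, ll_mix, bic_mix, bic_gauss)


def localization_score(fit: FrameModelFit, frame: FrameObservation) -> float:
    """Expected nuclear share of the frame's total intensity, in [0, 1].

    ``sum_p P(nuclear | I_p) * I_p / sum_p I_p``; 0 when no nucleus is
    visible.  Higher scores mean the protein sits more in the nucleus.
    """
    total = float(frame.pixels.sum())
    if total <= 0:
        raise ValueError("zero total intensity")
    if not fit.nucleus_visible:
        return 0.0
    score = float((fit.posterior * frame.pixels).sum() / total)
    return min(max(score, 0.0), 1.0)


@dataclass
class PulseTrace:
    """Per-frame localization scores for one tracked cell."""

    cell_id: str
    scores: np.ndarray
    frame_interval_min: float = 2.5

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        ok = self.scores[~np.isnan(self.scores)]
        if ok.size and (ok.min() < 0 or ok.max() > 1):
            raise ValueError("scores must lie in [0, 1]")


def score_trace(frames: list[FrameObservation], w_min: float = DEFAULT_W_MIN) -> PulseTrace:
    """Localization score per frame, in frame order; gaps become NaN."""
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    frames = sorted(frames, key=lambda f: f.frame)
    first, last = frames[0].frame, frames[-1].frame
    scores = np.full(last - first + 1, np.nan)
    for f in frames:
        fit = fit_frame_model(f, w_min=w_min)
        scores[f.frame - first] = localization_score(fit, f)
    return PulseTrace(frames[0].cell_id, scores, frames[0].frame_interval_min)


def pulse_durations(
    trace: PulseTrace, min_prominence: float = DEFAULT_MIN_PROMINENCE
) -> np.ndarray:
    """Durations (minutes) of score pulses.

    Peaks are found with a prominence threshold; each duration is the peak
    width at half prominence, with crossing positions linearly interpolated
    between frames, times the frame interval.  Missing frames are linearly
    interpolated for detection only.
    """
    s = np.asarray(trace.scores, dtype=float)
    if s.size < 3:
        raise ValueError("need at least 3 frames")
    nanmask = np.isnan(s)
    if nanmask.all():
        return np.array([])
    if nanmask.any():
        idx = np.arange(s.size)
        s = np.interp(idx, idx[~nanmask], s[~nanmask])
    peaks, props = find_peaks(s, prominence=min_prominence)
    if peaks.size == 0:
        return np.array([])
    widths, _, _, _ = peak_widths(
        s, peaks, rel_height=0.5,
        prominence_data=(props["prominences"], props["left_bases"], props["right_bases"]),
    )
    return widths * trace.frame_interval_min


def compare_durations(
    group_a, group_b, alternative: str = "b_greater", pooled: bool = True
) -> tuple[float, float]:
    """Two-sample t-test of pulse durations, one-sided by default.

    Returns ``(t, p)`` where t is the pooled-variance statistic for
    ``mean(b) - mean(a)`` and p the one-sided tail probability under the t
    distribution with n_a + n_b - 2 degrees of freedom (Welch with
    ``pooled=False``).  ``alternative`` is ``"b_greater"`` or
    ``"a_greater"``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 durations")
    if alternative not in ("b_greater", "a_greater"):
        raise ValueError("alternative must be 'b_greater' or 'a_greater'")
    diff = b.mean() - a.mean()
    if alternative == "a_greater":
        diff = -diff
    if pooled:
        df = a.size + b.size - 2
        s2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
        if s2 <= 0:
            raise ValueError("zero pooled variance")
        se = np.sqrt(s2 * (1.0 / a.size + 1.0 / b.size))
    else:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        if va + vb <= 0:
            raise ValueError("zero variance")
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    t = float(diff / se)
    p = float(t_dist.sf(t, df))
    return t, p
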