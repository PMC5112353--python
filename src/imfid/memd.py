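"""Multivariate empirical mode decomposition (MEMD) and its noise-assisted
variant (NA-MEMD).

MEMD extracts joint oscillatory modes (IMFs) from an n-variate signal by
projecting it along a quasi-uniform set of direction vectors on the unit
(n-1)-sphere, interpolating the multivariate samples at each projection's
maxima with cubic splines, and averaging the directional envelopes to form a
local mean that is subtracted iteratively (sifting).  Appending independent
white-noise channels before decomposition (NA-MEMD) exploits the quasi-dyadic
filter-bank behaviour of MEMD on white noise to align scales across channels
and reduce mode mixing.

Sifting stops when either (a) every projected candidate has extrema and
zero-crossing counts differing by at most one for ``tau`` consecutive
iterations, or (b) the evaluation function f(t) = |m(t)| / rho(t) -- local
mean magnitude over directional envelope amplitude -- falls below the
threshold ``gamma`` on time-average.  This moderate sifting depth is what
gives the decomposition its quasi-dyadic filter-bank behaviour on white
noise (each successive scale carries roughly half the centre frequency of
the previous one); sifting much deeper narrows the per-scale bands and
destroys the dyadic alignment that the noise-assisted variant relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .signals import MultichannelSignal, NoiseSpec, concat_channels, make_noise

__all__ = ["SiftConfig", "IMFDecomposition", "direction_set", "local_mean",
           "sift_stop", "memd", "na_memd"]

_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47, 53, 59, 61)


@dataclass
class SiftConfig:
    """Sifting hyperparameters.

    kappa : number of projection directions (>= 2*(n_channels-1) recommended).
    tau : consecutive iterations the extrema/zero-crossing criterion must
        hold before sifting stops.
    gamma : threshold on the envelope evaluation function f(t) = |m|/rho;
        sifting stops once the time-average of f falls to gamma or below.
    max_sift_iters, max_imfs : safety caps.
    """

    kappa: int = 64
    tau: int = 5
    gamma: float = 0.075
    max_sift_iters: int = 50
    max_imfs: int | None = 12

    def __post_init__(self) -> None:
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")


@dataclass
class IMFDecomposition:
    """Joint IMFs of a multivariate signal.

    imfs : ndarray (n_channels, J, L) -- scale j of channel c is imfs[c, j].
    residual : ndarray (n_channels, L).
    The input is recovered exactly as ``imfs.sum(axis=1) + residual``.
    """

    imfs: np.ndarray
    residual: np.ndarray
    fs: float
    config: SiftConfig
    noise_rows: list[int] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.imfs.shape[0]

    @property
    def n_scales(self) -> int:
        return self.imfs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.imfs.shape[2]

    @property
    def signal_rows(self) -> list[int]:
        noise = set(self.noise_rows)
        return [c for c in range(self.n_channels) if c not in noise]

    def reconstruct(self) -> np.ndarray:
        return self.imfs.sum(axis=1) + self.residual


def _radical_inverse(i: int, base: int) -> float:
    inv, f = 0.0, 1.0 / base
    while i > 0:
        inv += (i % base) * f
        i //= base
        f /= base
    return inv


def direction_set(kappa: int, dim: int) -> np.ndarray:
    """Quasi-uniform unit direction vectors on the (dim-1)-sphere.

    A Hammersley low-discrepancy sequence in [0,1]^(dim-1) is mapped through
    the inverse CDFs of the spherical-coordinate marginals: the cosine of the
    j-th polar angle follows a symmetric Beta law (shape (dim-j)/2), the
    azimuth is uniform.  The area-preserving map keeps the sequence's
    equidistribution, so the directions spread far more evenly than i.i.d.
    random ones.  Deterministic in (kappa, dim).
    """
    if dim < 2:
        raise ValueError("directions require dimension >= 2")
    if kappa < 1:
        raise ValueError("kappa must be >= 1")
    if dim - 2 > len(_PRIMES):
        raise ValueError(f"dimension {dim} exceeds supported maximum {len(_PRIMES) + 2}")
    from scipy.special import betaincinv

    u = np.empty((kappa, dim - 1))
    u[:, 0] = (np.arange(kappa) + 0.5) / kappa
    if dim == 3:
        # classic two-coordinate Hammersley: stratified axis + base-2 radical inverse
        u[:, 1] = [_radical_inverse(i + 1, 2) for i in range(kappa)]
    elif dim > 3:
        # scrambled Halton for the remaining coordinates: plain radical-inverse
        # sequences in large prime bases are strongly correlated at small
        # sample counts, which would bias the direction coverage
        from scipy.stats import qmc

        h = qmc.Halton(d=dim - 2, scramble=True, seed=0)
        u[:, 1:] = h.random(kappa)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    out = np.empty((kappa, dim))
    sin_prod = np.ones(kappa)
    for j in range(dim - 2):
        a = (dim - 1 - j) / 2.0
        cos_t = 1.0 - 2.0 * betaincinv(a, a, u[:, j])
        out[:, j] = sin_prod * cos_t
        sin_prod = sin_prod * np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
    phi = 2.0 * np.pi * u[:, dim - 2]
    out[:, dim - 2] = sin_prod * np.cos(phi)
    out[:, dim - 1] = sin_prod * np.sin(phi)
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _local_maxima(p: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima of a 1-D array, plateau-tolerant."""
    # Collapse exact ties by comparing against previous/next differing value.
    d = np.diff(p)
    rising = d > 0
    falling = d < 0
    idx = np.nonzero(rising[:-1] & falling[1:])[0] + 1
    return idx


def _count_extrema_zero_crossings(p: np.ndarray) -> tuple[int, int]:
    d = np.diff(p)
    sgn = np.sign(d)
    sgn = sgn[sgn != 0]
    n_ext = int(np.sum(sgn[:-1] != sgn[1:])) if sgn.size > 1 else 0
    s = np.sign(p)
    s = s[s != 0]
    n_zc = int(np.sum(s[:-1] != s[1:])) if s.size > 1 else 0
    return n_ext, n_zc


def _envelope(x: np.ndarray, t: np.ndarray, max_idx: np.ndarray) -> np.ndarray | None:
    """Cubic-spline envelope of multivariate samples at projection extrema,
    with 2-extrema mirror extension at each boundary."""
    if max_idx.size < 2:
        return None
    L = x.shape[1]
    ti = max_idx.astype(float)
    yi = x[:, max_idx]
    # Mirror up to two extrema about each endpoint to tame spline ends.
    k = min(2, max_idx.size)
    t_left = 2 * t[0] - ti[:k][::-1] - 0.0
    y_left = yi[:, :k][:, ::-1]
    t_right = 2 * t[-1] - ti[-k:][::-1]
    y_right = yi[:, -k:][:, ::-1]
    tt = np.concatenate([t_left, ti, t_right])
    yy = np.concatenate([y_left, yi, y_right], axis=1)
    order = np.argsort(tt)
    tt, yy = tt[order], yy[:, order]
    keep = np.concatenate([[True], np.diff(tt) > 0])
    tt, yy = tt[keep], yy[:, keep]
    if tt.size < 2:
        return None
    cs = CubicSpline(tt, yy, axis=1, bc_type="natural")
    return cs(t)


def local_mean(x: np.ndarray, directions: np.ndarray) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Local mean m(t) and scalar envelope amplitude rho(t) of a
    multivariate candidate.

    For each direction the candidate is projected and the multivariate
    samples are spline-interpolated at the projection's maxima and minima,
    giving upper/lower directional envelopes.  The directional mean is their
    average and the directional amplitude is half their gap; m(t) and rho(t)
    average these over directions, rho collapsed across channels by the
    Euclidean norm.  Directions whose projections have too few extrema are
    skipped (a constant projection contributes the signal itself as its own
    degenerate envelope).

    Returns (m, rho) with m of shape (n_channels, L) and rho of shape (L,),
    or (None, None) when fewer than half the directions produced envelopes.
    """
    n, L = x.shape
    t = np.arange(L, dtype=float)
    proj = directions @ x  # (kappa, L)
    means, amps = [], []
    for k in range(directions.shape[0]):
        p = proj[k]
        if np.ptp(p) < 1e-12 * (1.0 + np.abs(p).max()):
            means.append(x)
            amps.append(np.zeros(L))
            continue
        e_max = _envelope(x, t, _local_maxima(p))
        e_min = _envelope(x, t, _local_maxima(-p))
        if e_max is None or e_min is None:
            continue
        means.append(0.5 * (e_max + e_min))
        amps.append(np.linalg.norm(0.5 * (e_max - e_min), axis=0))
    if len(means) < directions.shape[0] // 2:
        return None, None
    m = np.mean(means, axis=0)
    rho = np.mean(amps, axis=0)
    return m, rho


def _criterion_counts(proj: np.ndarray) -> bool:
    """True when every projected signal has |#extrema - #zero crossings| <= 1."""
    for row in proj:
        n_ext, n_zc = _count_extrema_zero_crossings(row)
        if abs(n_ext - n_zc) > 1:
            return False
    return True


def sift_stop(proj: np.ndarray, m: np.ndarray, rho: np.ndarray,
              state: dict, config: SiftConfig) -> bool:
    """Combined stoppage decision for one sifting iteration.

    ``state['count']`` carries the consecutive-satisfaction counter for the
    extrema/zero-crossing criterion across iterations; ``state['iters']`` the
    iteration number.  Either criterion suffices; the iteration cap always
    stops.
    """
    state["iters"] = state.get("iters", 0) + 1
    if _criterion_counts(proj):
        state["count"] = state.get("count", 0) + 1
    else:
        state["count"] = 0
    if state["count"] >= config.tau:
        return True
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.abs(np.linalg.norm(m, axis=0) / rho)
    f = np.nan_to_num(f, nan=0.0, posinf=np.inf)
    if np.mean(f) <= config.gamma:
        return True
    return state["iters"] >= config.max_sift_iters


def _is_monotonic_residual(x: np.ndarray, directions: np.ndarray) -> bool:
    proj = directions @ x
    for row in proj:
        n_ext, _ = _count_extrema_zero_crossings(row)
        if n_ext >= 3:
            return False
    return True


def memd(signal: MultichannelSignal, config: SiftConfig | None = None) -> IMFDecomposition:
    """Decompose a multivariate signal into joint IMFs plus a residual.

    Repeatedly sifts the running residual (subtracting the directional-
    envelope local mean until :func:`sift_stop` fires), records the candidate
    as the next IMF, and stops when the residual is monotone along every
    projection or ``max_imfs`` is reached.  The decomposition telescopes:
    the IMFs and residual sum back to the input exactly.
    """
    config = config or SiftConfig()
    x = signal.data
    n, L = x.shape
    if n < 2:
        raise ValueError("MEMD requires at least 2 channels")
    if L < 16:
        raise ValueError("MEMD requires at least 16 samples")
    dirs = direction_set(config.kappa, n)
    residual = x.copy()
    imfs: list[np.ndarray] = []
    max_imfs = config.max_imfs or np.inf
    while len(imfs) < max_imfs and not _is_monotonic_residual(residual, dirs):
        h = residual.copy()
        state: dict = {}
        while True:
            m, rho = local_mean(h, dirs)
            if m is None:
                break
            if sift_stop(dirs @ h, m, rho, state, config):
                break
            h = h - m
        imfs.append(h)
        residual = residual - h
    J = len(imfs)
    stack = (np.stack(imfs, axis=1) if J else np.empty((n, 0, L)))
    return IMFDecomposition(imfs=stack, residual=residual, fs=signal.fs,
                            config=config, noise_rows=list(signal.noise_rows))


def na_memd(signal: MultichannelSignal, noise_spec: NoiseSpec,
            config: SiftConfig | None = None) -> IMFDecomposition:
    """Noise-assisted MEMD: append independent white-noise reference channels
    and decompose the composite jointly.

    The returned decomposition covers all n+l channels, with ``noise_rows``
    identifying the appended reference block so callers can separate
    signal-channel IMFs from noise-channel IMFs at each scale.
    """
    noise = make_noise(noise_spec, signal.n_samples, signal)
    composite = concat_channels(signal, noise)
    return memd(composite, config)
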