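"""Synthetic data generators with ground truth.

Every input the analysis pipeline consumes can be simulated here:
miniature-event traces (Poisson arrivals, lognormal amplitudes,
biexponential kernels in Gaussian noise), 60 Hz depression trains from a
depletion--replenishment quantal model, genotype screens in which
philanthotoxin acts as a multiplicative quantal-size reduction, and
two-channel puncta point sets inside bouton polygons, optionally rendered
through a Gaussian PSF.

All generators are deterministic under a fixed seed and return the ground
truth alongside the data so that detectors and estimators can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely import contains_xy

__all__ = [
    "MiniSimParams",
    "QuantalModelParams",
    "ScreenSimParams",
    "BoutonSimParams",
    "Trace",
    "MiniGroundTruth",
    "TrainGroundTruth",
    "BoutonGeometry",
    "biexp_kernel",
    "simulate_minis",
    "simulate_trains",
    "simulate_screen",
    "simulate_boutons",
    "simulate_php_experiment",
    "simulate_nnd_dataset",
    "render_puncta_image",
]


# ---------------------------------------------------------------------------
# Containers


@dataclass(frozen=True)
class Trace:
    """Uniformly sampled current/voltage signal.

    samples : signal values (mV or nA)
    dt : sampling interval in seconds
    units : "mV" or "nA"
    polarity : +1 for upward events, -1 for downward (inward-current) events
    """

    samples: np.ndarray
    dt: float
    units: str = "nA"
    polarity: int = -1

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt


@dataclass(frozen=True)
class MiniGroundTruth:
    """True onset times (s) and amplitudes (signal units) of injected minis."""

    times: np.ndarray
    amplitudes: np.ndarray


@dataclass(frozen=True)
class TrainGroundTruth:
    """True quantal parameters behind a simulated train set."""

    n0: float
    pr: float
    q: float
    k_replenish: float


@dataclass(frozen=True)
class BoutonGeometry:
    """Bouton boundary polygon with two labeled point channels (nm units)."""

    polygon: Polygon
    reference: np.ndarray  # (n_ref, 2)
    target: np.ndarray  # (n_target, 2)
    bouton_id: str = "bouton"


# ---------------------------------------------------------------------------
# Parameter blocks


@dataclass(frozen=True)
class MiniSimParams:
    """Parameters for miniature-event trace simulation.

    Defaults describe a clean mEPSC recording: 2 Hz spontaneous rate,
    unit mean amplitude with 10% between-event CV (right-skewed lognormal;
    narrow by physiological standards, chosen so the standard detection
    operating point -- Clements-Bekkers criterion threshold 4 at amplitude
    SNR 5 -- sits above the amplitude distribution's lower tail, see
    docs/methods.md), 0.5 ms
    rise / 5 ms decay kernel, and noise giving an amplitude SNR of 5 at
    10 kHz sampling.
    """

    rate: float = 2.0  # events / s
    amp_mean: float = 1.0  # signal units
    amp_cv: float = 0.10
    rise_tau: float = 0.5  # ms
    decay_tau: float = 5.0  # ms
    noise_sd: float = 0.2  # signal units
    duration: float = 60.0  # s
    dt: float = 1e-4  # s
    polarity: int = -1
    seed: int = 0

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if self.amp_mean <= 0:
            raise ValueError("amp_mean must be positive")
        if self.amp_cv < 0 or self.noise_sd < 0:
            raise ValueError("amp_cv and noise_sd must be >= 0")
        if not 0 < self.rise_tau < self.decay_tau:
            raise ValueError("require 0 < rise_tau < decay_tau")
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")


@dataclass(frozen=True)
class QuantalModelParams:
    """Depletion--replenishment quantal model for high-frequency trains.

    A_i = q * pr * N_i * (1 + eps_i), eps_i ~ Normal(0, trial_noise_cv);
    N_{i+1} = N_i(1-pr) + k_replenish * dt * (N0 - N_i(1-pr)), clipped to
    [0, N0]; N_1 = N0 and dt = 1/freq.
    """

    n0: float = 500.0  # vesicles in the readily releasable pool
    pr: float = 0.5  # release probability per stimulus
    q: float = 1.0  # quantal size, signal units per vesicle
    k_replenish: float = 0.0  # fractional recovery toward N0 per second
    n_stim: int = 60
    freq: float = 60.0  # Hz
    n_trains: int = 5
    trial_noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.pr <= 1:
            raise ValueError("pr must be in [0, 1]")
        if self.n0 < 1 or self.q <= 0:
            raise ValueError("n0 >= 1 and q > 0 required")
        if self.k_replenish < 0 or self.trial_noise_cv < 0:
            raise ValueError("k_replenish and trial_noise_cv must be >= 0")
        if self.n_stim < 1 or self.n_trains < 1 or self.freq <= 0:
            raise ValueError("n_stim, n_trains >= 1 and freq > 0 required")


@dataclass(frozen=True)
class ScreenSimParams:
    """Genotype screen: per-line NMJ means under PhTX plus WT references.

    PhTX scales quantal size by ``phtx_q_scale`` (default 0.6, a ~40%
    mini-amplitude reduction). PHP-competent lines scale quantal content by
    the reciprocal so the evoked amplitude is conserved; PHP-deficient lines
    do not, so their EPSC drops by the same factor as the quantal size.
    """

    n_lines: int = 180
    wt_mepsp: float = 1.0  # mV
    wt_epsc: float = 60.0  # nA
    phtx_q_scale: float = 0.6
    frac_php_deficient: float = 0.0
    between_nmj_cv: float = 0.15
    n_wt_ref: int = 16  # NMJs in each WT reference group
    seed: int = 0

    def __post_init__(self):
        if self.n_lines < 0:
            raise ValueError("n_lines must be >= 0")
        if not 0 < self.phtx_q_scale <= 1:
            raise ValueError("phtx_q_scale must be in (0, 1]")
        if not 0 <= self.frac_php_deficient <= 1:
            raise ValueError("frac_php_deficient must be in [0, 1]")
        if self.between_nmj_cv < 0:
            raise ValueError("between_nmj_cv must be >= 0")


@dataclass(frozen=True)
class BoutonSimParams:
    """Two-channel puncta placement inside a bouton polygon (nm units)."""

    polygon: tuple = ()  # vertex list ((x, y), ...)
    n_ref: int = 12
    n_target: int = 12
    coupling_fraction: float = 0.0
    coupling_sigma: float = 50.0  # nm
    seed: int = 0

    def __post_init__(self):
        if self.n_ref < 0 or self.n_target < 0:
            raise ValueError("point counts must be >= 0")
        if not 0 <= self.coupling_fraction <= 1:
            raise ValueError("coupling_fraction must be in [0, 1]")
        if self.coupling_sigma < 0:
            raise ValueError("coupling_sigma must be >= 0")
        poly = Polygon(self.polygon)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("polygon must be simple with positive area")


# ---------------------------------------------------------------------------
# Helpers


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Draw lognormal values with the given arithmetic mean and CV."""
    if cv == 0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def biexp_kernel(rise_tau: float, decay_tau: float, length: float, dt: float) -> np.ndarray:
    """Peak-normalised biexponential kernel w(t) = (1-e^(-t/tr)) e^(-t/td).

    Taus and length in ms, dt in seconds. The kernel starts at 0 and its
    maximum is exactly 1.
    """
    if not 0 < rise_tau < decay_tau:
        raise ValueError("require 0 < rise_tau < decay_tau")
    n = max(int(round(length * 1e-3 / dt)), 2)
    t = np.arange(n) * dt * 1e3  # ms
    w = (1.0 - np.exp(-t / rise_tau)) * np.exp(-t / decay_tau)
    peak = w.max()
    if peak <= 0:
        raise ValueError("kernel too short to reach a peak")
    return w / peak


def uniform_in_polygon(polygon: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """n independent uniform draws inside a polygon via rejection sampling."""
    if polygon.area <= 0:
        raise ValueError("polygon must have positive area")
    minx, miny, maxx, maxy = polygon.bounds
    out = np.empty((n, 2))
    filled = 0
    # acceptance ratio = area / bbox area; draw in batches
    frac = polygon.area / ((maxx - minx) * (maxy - miny))
    while filled < n:
        m = max(int((n - filled) / max(frac, 1e-3) * 1.2), 16)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        ok = contains_xy(polygon, xs, ys)
        take = min(int(ok.sum()), n - filled)
        out[filled : filled + take, 0] = xs[ok][:take]
        out[filled : filled + take, 1] = ys[ok][:take]
        filled += take
    return out


# ---------------------------------------------------------------------------
# Generators


def simulate_minis(params: MiniSimParams) -> tuple[Trace, MiniGroundTruth]:
    """Simulate a trace of Poisson-arriving miniature events in noise.

    Events are biexponential kernels (peak-normalised) scaled by lognormal
    amplitudes, summed onto Gaussian baseline noise. Returns the trace and
    the exact onset times / amplitudes.
    """
    rng = np.random.default_rng(params.seed)
    n_samples = int(round(params.duration / params.dt))
    n_events = rng.poisson(params.rate * params.duration)
    onsets = np.sort(rng.uniform(0.0, params.duration, n_events))
    amps = _lognormal(rng, params.amp_mean, params.amp_cv, n_events)

    kernel = biexp_kernel(
        params.rise_tau, params.decay_tau, length=params.rise_tau + 6 * params.decay_tau, dt=params.dt
    )
    signal = np.zeros(n_samples)
    idx = np.round(onsets / params.dt).astype(int)
    for i, a in zip(idx, amps):
        if i >= n_samples:
            continue
        k = min(len(kernel), n_samples - i)
        signal[i : i + k] += a * kernel[:k]
    if params.noise_sd > 0:
        signal += rng.normal(0.0, params.noise_sd, n_samples)
    trace = Trace(samples=params.polarity * signal, dt=params.dt, polarity=params.polarity)
    return trace, MiniGroundTruth(times=onsets, amplitudes=amps)


def _iterate_train(params: QuantalModelParams, eps: np.ndarray) -> np.ndarray:
    """One train of the depletion--replenishment recurrence."""
    dt = 1.0 / params.freq
    amps = np.empty(params.n_stim)
    n = float(params.n0)
    for i in range(params.n_stim):
        amps[i] = params.q * params.pr * n * (1.0 + eps[i])
        remaining = n * (1.0 - params.pr)
        n = remaining + params.k_replenish * dt * (params.n0 - remaining)
        n = min(max(n, 0.0), params.n0)
    return amps


def simulate_trains(
    params: QuantalModelParams, cell_id: str = "cell0"
) -> tuple[pd.DataFrame, TrainGroundTruth]:
    """Simulate high-frequency stimulus trains from the quantal model.

    Returns a long-format table (cell_id, train_id, stimulus_index,
    amplitude) with 1-based stimulus indices, and the true parameters.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for tr in range(params.n_trains):
        eps = (
            rng.normal(0.0, params.trial_noise_cv, params.n_stim)
            if params.trial_noise_cv > 0
            else np.zeros(params.n_stim)
        )
        amps = _iterate_train(params, eps)
        for i, a in enumerate(amps):
            rows.append((cell_id, tr, i + 1, a))
    df = pd.DataFrame(rows, columns=["cell_id", "train_id", "stimulus_index", "amplitude"])
    truth = TrainGroundTruth(n0=params.n0, pr=params.pr, q=params.q, k_replenish=params.k_replenish)
    return df, truth


def _nmjs_per_line(rng: np.random.Generator, n_lines: int) -> np.ndarray:
    """Per-line NMJ counts: 3 + Poisson(1) truncated at 12 (mean ~4, range 3-12)."""
    counts = 3 + rng.poisson(1.0, n_lines)
    return np.minimum(counts, 12)


def simulate_screen(params: ScreenSimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a PhTX genotype screen plus WT reference groups.

    Each transgenic line is recorded under PhTX: its mean mEPSP per NMJ is
    wt_mepsp * phtx_q_scale * (1 + noise) and its mean EPSC per NMJ is
    wt_epsc * s * (1 + noise) with s = 1 (PHP-competent) or s = phtx_q_scale
    (PHP-deficient). WT reference groups with and without PhTX are appended.

    Returns (screen table, per-line ground truth).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_lines
    deficient = rng.random(n) < params.frac_php_deficient
    nmjs = _nmjs_per_line(rng, n)
    cv = params.between_nmj_cv

    rows = []
    for li in range(n):
        line = f"line{li:03d}"
        cls = "php_deficient" if deficient[li] else "php_competent"
        s = params.phtx_q_scale if deficient[li] else 1.0
        for nm in range(int(nmjs[li])):
            me = params.wt_mepsp * params.phtx_q_scale * (1 + rng.normal(0, cv))
            ep = params.wt_epsc * s * (1 + rng.normal(0, cv))
            rows.append((line, cls, "PhTX", nm, "mEPSP", me))
            rows.append((line, cls, "PhTX", nm, "EPSC", ep))
    # WT references: untreated and PhTX-treated (WT is PHP-competent)
    for cond, q_scale in (("control", 1.0), ("PhTX", params.phtx_q_scale)):
        for nm in range(params.n_wt_ref):
            me = params.wt_mepsp * q_scale * (1 + rng.normal(0, cv))
            ep = params.wt_epsc * (1 + rng.normal(0, cv))
            rows.append(("WT", "WT", cond, nm, "mEPSP", me))
            rows.append(("WT", "WT", cond, nm, "EPSC", ep))

    table = pd.DataFrame(
        rows, columns=["line_id", "genotype_class", "condition", "nmj_id", "modality", "value"]
    )
    truth = pd.DataFrame(
        {
            "line_id": [f"line{li:03d}" for li in range(n)],
            "php_deficient": deficient,
            "true_epsc_scale": np.where(deficient, params.phtx_q_scale, 1.0),
            "n_nmjs": nmjs,
        }
    )
    return table, truth


def simulate_php_experiment(
    php_competent: bool,
    n_per_arm: int = 20,
    wt_mepsc: float = 1.0,
    quantal_content: float = 50.0,
    phtx_q_scale: float = 0.6,
    between_nmj_cv: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a two-arm (control vs PhTX) experiment for one genotype.

    Returns per-NMJ rows (condition, modality {mini, evoked}, value).
    mEPSC and EPSC come from different NMJs, mirroring the experimental
    design in which quantal content mixes measurements across cells.
    """
    rng = np.random.default_rng(seed)
    cv = between_nmj_cv
    rows = []
    for cond in ("control", "PhTX"):
        q = wt_mepsc * (phtx_q_scale if cond == "PhTX" else 1.0)
        qc = quantal_content
        if cond == "PhTX" and php_competent:
            qc = quantal_content / phtx_q_scale  # homeostatic compensation
        epsc = q * qc
        for nm in range(n_per_arm):
            rows.append((cond, nm, "mini", q * (1 + rng.normal(0, cv))))
            rows.append((cond, nm, "evoked", epsc * (1 + rng.normal(0, cv))))
    return pd.DataFrame(rows, columns=["condition", "nmj_id", "modality", "value"])


def simulate_boutons(params: BoutonSimParams) -> tuple[BoutonGeometry, np.ndarray]:
    """Place two channels of puncta inside a bouton polygon.

    Reference points are uniform in the polygon. Each target point is,
    with probability ``coupling_fraction``, tethered to a uniformly chosen
    reference point plus isotropic Normal(0, coupling_sigma) displacement
    (redrawn until inside the polygon); otherwise uniform in the polygon.

    Returns the geometry and the per-target-point coupled flags.
    """
    poly = Polygon(params.polygon)
    rng = np.random.default_rng(params.seed)
    ref = uniform_in_polygon(poly, params.n_ref, rng)
    coupled = rng.random(params.n_target) < params.coupling_fraction
    if params.n_ref == 0:
        coupled[:] = False
    target = np.empty((params.n_target, 2))
    for j in range(params.n_target):
        if coupled[j]:
            anchor = ref[rng.integers(0, params.n_ref)]
            while True:
                p = anchor + rng.normal(0.0, params.coupling_sigma, 2)
                if contains_xy(poly, p[0], p[1]):
                    break
            target[j] = p
        else:
            target[j] = uniform_in_polygon(poly, 1, rng)[0]
    geom = BoutonGeometry(polygon=poly, reference=ref, target=target)
    return geom, coupled


def _jittered_circle(
    rng: np.random.Generator, radius_nm: float = 1250.0, n_vertices: int = 16, jitter: float = 0.2
) -> tuple:
    """A bouton-like simple polygon: circle with radial jitter (nm)."""
    ang = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = radius_nm * (1 + rng.uniform(-jitter, jitter, n_vertices))
    return tuple(zip(r * np.cos(ang), r * np.sin(ang)))


def simulate_nnd_dataset(
    n_nmjs: int = 10,
    boutons_per_nmj: int = 13,
    mean_puncta: float = 12.0,
    coupling_fraction: float = 0.0,
    coupling_sigma: float = 50.0,
    bouton_radius_nm: float = 1250.0,
    seed: int = 0,
) -> list[BoutonGeometry]:
    """Simulate a full NND dataset: NMJs of boutons with two puncta channels.

    Boutons are jittered circles of ~2.5 um diameter; per-channel puncta
    counts are Poisson(mean_puncta) with a floor of 1 so every bouton
    contributes an NND.
    """
    rng = np.random.default_rng(seed)
    boutons = []
    for nmj in range(n_nmjs):
        for b in range(boutons_per_nmj):
            poly = _jittered_circle(rng, radius_nm=bouton_radius_nm)
            n_ref = max(1, int(rng.poisson(mean_puncta)))
            n_target = max(1, int(rng.poisson(mean_puncta)))
            p = BoutonSimParams(
                polygon=poly,
                n_ref=n_ref,
                n_target=n_target,
                coupling_fraction=coupling_fraction,
                coupling_sigma=coupling_sigma,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            geom, _ = simulate_boutons(p)
            boutons.append(
                BoutonGeometry(
                    polygon=geom.polygon,
                    reference=geom.reference,
                    target=geom.target,
                    bouton_id=f"nmj{nmj:02d}_b{b:02d}",
                )
            )
    return boutons


def render_puncta_image(
    geometry: BoutonGeometry,
    psf_sigma: float = 60.0,
    pixel_size: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    pad_nm: float | None = None,
) -> tuple[np.ndarray, float]:
    """Render the two point channels as Gaussian spots on a pixel grid.

    Each point becomes an isotropic 2-D Gaussian of width ``psf_sigma`` (nm)
    with unit peak; channels are stacked as (2, H, W). The grid covers the
    polygon bounding box (padded by 3 sigma by default). Returns the image
    and the pixel size (nm per pixel, default 20).
    """
    if pixel_size <= 0 or psf_sigma <= 0:
        raise ValueError("pixel_size and psf_sigma must be positive")
    if pad_nm is None:
        pad_nm = 3 * psf_sigma
    minx, miny, maxx, maxy = geometry.polygon.bounds
    minx -= pad_nm
    miny -= pad_nm
    maxx += pad_nm
    maxy += pad_nm
    w = max(int(np.ceil((maxx - minx) / pixel_size)), 1)
    h = max(int(np.ceil((maxy - miny) / pixel_size)), 1)
    xs = minx + (np.arange(w) + 0.5) * pixel_size
    ys = miny + (np.arange(h) + 0.5) * pixel_size
    img = np.zeros((2, h, w))
    for ch, pts in enumerate((geometry.reference, geometry.target)):
        for px, py in np.atleast_2d(pts) if len(pts) else []:
            gx = np.exp(-0.5 * ((xs - px) / psf_sigma) ** 2)
            gy = np.exp(-0.5 * ((ys - py) / psf_sigma) ** 2)
            img[ch] += np.outer(gy, gx)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img += rng.normal(0.0, noise_sd, img.shape)
    return img, pixel_size
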