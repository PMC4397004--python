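"""Log-Gabor filter bank and two-dimensional phase congruency.

Phase congruency (PC) marks the pixels at which the Fourier components of
an image are maximally in phase, which happens at edges and line features
regardless of their contrast.  For every pixel x,

    PC(x) = sum_o floor( W_o(x) * sum_n A_no(x) dPhi_no(x) - T_o )
            ------------------------------------------------------ ,
                     sum_o sum_n A_no(x) + eps

where A_no and phi_no are the amplitude and local phase of the response of
a quadrature log-Gabor channel at wavelet scale n and orientation o,
dPhi_no = cos(phi_no - phibar) - |sin(phi_no - phibar)| penalises phase
deviation from the orientation's amplitude-weighted mean phase phibar,
W_o is a sigmoid weight that discounts pixels whose response is spread
over few filter scales, T_o is a Rayleigh-based noise threshold, the
floor clips negative values to zero, and eps avoids division by zero.
The measure is dimensionless and lies in [0, 1].

The radial filter is a log-Gabor: a Gaussian on the log-frequency axis,
G(w) = exp(-log(w/w0)^2 / (2 log(sigma)^2)) with sigma = kappa/w0 fixing
the octave bandwidth; it has zero DC gain at any bandwidth.  Angular
selectivity comes from a Gaussian in filter-orientation angle covering one
half-plane, so that the complex inverse transform of a filtered spectrum
yields the even (real) and odd (imaginary) quadrature responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit


@dataclass(frozen=True)
class PCParams:
    """Full parameter set of the phase-congruency model.

    Defaults are the tuned values for 256x256 chest-radiograph ROIs:
    5 scales x 6 orientations, smallest wavelength 8 px, scale multiplier
    3, bandwidth ratio sigma = 0.55 (about two octaves), angular
    interval/spread ratio d = 1, sigmoid gain 50 and cut-off 0.2, noise
    multiplier k = 2.
    """

    n: int = 5
    o: int = 6
    lambda_min: float = 8.0
    alpha: float = 3.0
    sigma: float = 0.55
    d: float = 1.0
    gamma: float = 50.0
    c: float = 0.2
    k: float = 2.0
    epsilon: float = 1e-4

    def __post_init__(self) -> None:
        if self.n < 1 or self.o < 1:
            raise ValueError("need at least one scale and one orientation")
        if not self.lambda_min > 2:
            raise ValueError("lambda_min must exceed 2 pixels (Nyquist)")
        if not self.alpha > 1:
            raise ValueError("alpha must exceed 1")
        if not 0 < self.sigma < 1:
            raise ValueError("sigma must lie in (0, 1)")
        if self.d <= 0 or self.gamma <= 0:
            raise ValueError("d and gamma must be positive")
        if not 0 <= self.c <= 1:
            raise ValueError("cut-off c must lie in [0, 1]")
        if self.k < 0:
            raise ValueError("noise multiplier k must be nonnegative")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")

    @property
    def wavelengths(self) -> np.ndarray:
        """Geometric wavelength sequence lambda_min * alpha**(i-1)."""
        return self.lambda_min * self.alpha ** np.arange(self.n)

    @property
    def orientations(self) -> np.ndarray:
        """Filter orientations (j-1) * pi / o, j = 1..o."""
        return np.arange(self.o) * np.pi / self.o


#: Generic starting parameter set for natural images, used as the seed of
#: the PSNR-guided coordinate search in :mod:`pclung.tune`.
GENERIC_START = PCParams(
    n=3, o=6, lambda_min=3.0, alpha=2.0, sigma=0.55, d=1.7, gamma=10.0, c=0.4, k=3.0
)

#: Alternative tuned set with sigmoid cut-off 0.3 (the PSNR optimum is flat
#: between c = 0.2 and c = 0.3; both are in routine use).
SELECTED_ALT = PCParams(c=0.3)


def log_gabor_transfer(w, w0: float, sigma: float):
    """Radial log-Gabor gain G(w) = exp(-log(w/w0)^2 / (2 log(sigma)^2)).

    G(w0) = 1, and the DC limit w -> 0 is exactly 0 for any bandwidth.
    """
    if not w0 > 0:
        raise ValueError("centre frequency w0 must be positive")
    if not 0 < sigma < 1:
        raise ValueError("sigma must lie in (0, 1)")
    w = np.asarray(w, dtype=float)
    out = np.zeros_like(w)
    pos = w > 0
    out[pos] = np.exp(-(np.log(w[pos] / w0) ** 2) / (2 * np.log(sigma) ** 2))
    if out.ndim == 0:
        return float(out)
    return out


def bandwidth_octaves(sigma: float) -> float:
    """Half-power bandwidth, in octaves, of the log-Gabor with ratio sigma.

    Solving G = 1/2 gives log2(w+/w-) = 2 sqrt(2 ln 2) |ln sigma| / ln 2;
    sigma = 0.55 gives approximately two octaves.
    """
    if not 0 < sigma < 1:
        raise ValueError("sigma must lie in (0, 1)")
    return 2.0 * np.sqrt(2 * np.log(2)) * abs(np.log(sigma)) / np.log(2)


@dataclass
class FilterBank:
    """Frequency-domain log-Gabor bank: gains[scale, orientation, :, :]."""

    gains: np.ndarray  # (n, o, rows, cols), real in [0, 1]
    params: PCParams
    shape: tuple[int, int]

    @property
    def n_channels(self) -> int:
        return self.gains.shape[0] * self.gains.shape[1]


def build_filter_bank(params: PCParams, shape: tuple[int, int]) -> FilterBank:
    """Build the n x o log-Gabor bank on the FFT grid of ``shape``.

    Channel (i, j) is the radial log-Gabor at centre wavelength
    lambda_min * alpha**(i-1) times an angular Gaussian centred on
    orientation (j-1) * pi / o with angular SD (pi/o) / d.  The angular
    term covers a single half-plane so the filtered spectrum is analytic
    (even response = real part, odd = imaginary part).  The DC bin has
    zero gain in every channel.
    """
    rows, cols = shape
    lam = params.wavelengths
    if lam[-1] > max(shape):
        warnings.warn(
            f"largest wavelength {lam[-1]:.0f} px exceeds image extent {max(shape)}",
            stacklevel=2,
        )
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.hypot(fy, fx)
    radius[0, 0] = 1.0  # avoid log(0); gain overwritten below
    theta = np.arctan2(-fy, fx)  # image y-axis points down
    sin_t, cos_t = np.sin(theta), np.cos(theta)

    sigma_theta = (np.pi / params.o) / params.d
    gains = np.empty((params.n, params.o, rows, cols))
    radial = np.empty((params.n, rows, cols))
    for i, lam_i in enumerate(lam):
        radial[i] = log_gabor_transfer(radius, 1.0 / lam_i, params.sigma)
        radial[i, 0, 0] = 0.0
    for j, ang in enumerate(params.orientations):
        ds = sin_t * np.cos(ang) - cos_t * np.sin(ang)
        dc = cos_t * np.cos(ang) + sin_t * np.sin(ang)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta**2) / (2 * sigma_theta**2))
        for i in range(params.n):
            gains[i, j] = radial[i] * spread
    return FilterBank(gains=gains, params=params, shape=(rows, cols))


@dataclass
class ChannelResponses:
    """Complex quadrature responses per channel.

    ``responses[n, o]`` holds even + i*odd; amplitude and phase follow as
    modulus and argument (phase of a zero response is 0 by convention).
    """

    responses: np.ndarray  # complex, (n, o, rows, cols)
    params: PCParams

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.responses)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.responses)


def channel_responses(image: np.ndarray, bank: FilterBank) -> ChannelResponses:
    """Filter the image with every channel by frequency-domain product."""
    image = np.asarray(image, dtype=float)
    if image.shape != bank.shape:
        raise ValueError(f"image shape {image.shape} does not match bank {bank.shape}")
    spectrum = np.fft.fft2(image)
    resp = np.fft.ifft2(spectrum[None, None] * bank.gains, axes=(-2, -1))
    return ChannelResponses(responses=resp, params=bank.params)


def phase_deviation(phi, phi_bar):
    """dPhi = cos(phi - phibar) - |sin(phi - phibar)|, in [-sqrt(2), 1].

    Equals 1 at zero deviation, 0 at pi/4 and -1 at pi/2; symmetric in the
    sign of the deviation.
    """
    delta = np.asarray(phi, dtype=float) - np.asarray(phi_bar, dtype=float)
    return np.cos(delta) - np.abs(np.sin(delta))


def rayleigh_threshold(amplitudes: np.ndarray, k: float) -> float:
    """Noise threshold mu_R + k*sigma_R from a Rayleigh amplitude sample.

    The Rayleigh scale is estimated robustly from the sample median,
    s = median / sqrt(2 ln 2); then mu_R = s sqrt(pi/2) and
    sigma_R = s sqrt(2 - pi/2).  An all-zero sample yields 0.
    """
    if k < 0:
        raise ValueError("k must be nonnegative")
    med = float(np.median(np.asarray(amplitudes, dtype=float)))
    scale = med / np.sqrt(2 * np.log(2))
    mu = scale * np.sqrt(np.pi / 2)
    sd = scale * np.sqrt(2 - np.pi / 2)
    return mu + k * sd


def noise_threshold(responses: ChannelResponses, k: float, orientation: int) -> float:
    """T_o estimated from the smallest-scale amplitudes at one orientation."""
    return rayleigh_threshold(np.abs(responses.responses[0, orientation]), k)


def sigmoid_weight(s, gamma: float, c: float):
    """Frequency-spread weight W = 1 / (1 + exp(gamma * (c - s))).

    Monotone increasing in the spread s, equal to 1/2 at s = c.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return expit(gamma * (np.asarray(s, dtype=float) - c))


@dataclass
class PCMap:
    """Phase congruency map with its per-orientation diagnostics."""

    pc: np.ndarray  # (rows, cols) in [0, 1]
    noise_thresholds: np.ndarray  # (o,)
    weights: np.ndarray  # (o, rows, cols)
    mean_phase: np.ndarray  # (o, rows, cols)
    amplitudes: np.ndarray  # (n, o, rows, cols)
    params: PCParams

    @property
    def channel_energies(self) -> np.ndarray:
        """Mean squared amplitude of each of the n*o channels."""
        return (self.amplitudes**2).mean(axis=(-2, -1)).ravel()


def phase_congruency_map(
    image: np.ndarray,
    params: PCParams | None = None,
    *,
    noise_mode: str = "rayleigh",
    extend: str = "symmetric",
) -> PCMap:
    """Compute the phase congruency map of an image.

    The input is standardised to zero mean and unit variance before
    filtering, which makes PC exactly invariant to affine intensity
    changes a*I + b (a > 0) and gives eps and the noise thresholds a fixed
    meaning relative to signal amplitude; a constant image yields an
    all-zero map.  ``extend='symmetric'`` mirrors the image to double size
    before the FFT to suppress wrap-around edges (set ``'none'`` for plain
    periodic boundaries).  ``noise_mode`` is ``'rayleigh'`` (threshold
    T_o = mu_R + k sigma_R estimated per orientation) or ``'none'``
    (T_o = 0, noise compensation off).
    """
    if params is None:
        params = PCParams()
    if noise_mode not in ("rayleigh", "none"):
        raise ValueError("noise_mode must be 'rayleigh' or 'none'")
    if extend not in ("symmetric", "none"):
        raise ValueError("extend must be 'symmetric' or 'none'")
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")

    rows, cols = image.shape
    sd = image.std()
    if sd == 0:
        zo = np.zeros((params.o, rows, cols))
        return PCMap(
            pc=np.zeros((rows, cols)),
            noise_thresholds=np.zeros(params.o),
            weights=zo,
            mean_phase=zo.copy(),
            amplitudes=np.zeros((params.n, params.o, rows, cols)),
            params=params,
        )
    work = (image - image.mean()) / sd
    if extend == "symmetric":
        work = np.pad(work, ((0, rows), (0, cols)), mode="symmetric")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # oversized wavelengths are benign here
        bank = build_filter_bank(params, work.shape)
    resp = channel_responses(work, bank).responses  # (n, o, R, C)
    even, odd = resp.real, resp.imag
    amp = np.abs(resp)

    eps = params.epsilon
    sum_amp_o = amp.sum(axis=0)  # (o, R, C)
    sum_even = even.sum(axis=0)
    sum_odd = odd.sum(axis=0)
    energy_norm = np.hypot(sum_even, sum_odd)
    mean_e = sum_even / (energy_norm + eps)
    mean_o = sum_odd / (energy_norm + eps)
    mean_phase = np.arctan2(sum_odd, sum_even)

    # sum_n A * dPhi via the quadrature identity
    # A cos(dphi) = e*mean_e + o*mean_o ; A |sin(dphi)| = |e*mean_o - o*mean_e|
    energy = (even * mean_e[None] + odd * mean_o[None]) - np.abs(
        even * mean_o[None] - odd * mean_e[None]
    )
    energy = energy.sum(axis=0)  # (o, R, C)

    a_max = amp.max(axis=0)
    spread = sum_amp_o / (params.n * (a_max + eps))
    weights = sigmoid_weight(spread, params.gamma, params.c)

    thresholds = np.zeros(params.o)
    if noise_mode == "rayleigh":
        for j in range(params.o):
            thresholds[j] = rayleigh_threshold(amp[0, j], params.k)

    numerator = np.maximum(weights * energy - thresholds[:, None, None], 0.0).sum(axis=0)
    pc = numerator / (sum_amp_o.sum(axis=0) + eps)

    sl = (slice(0, rows), slice(0, cols))
    return PCMap(
        pc=pc[sl],
        noise_thresholds=thresholds,
        weights=weights[(slice(None),) + sl],
        mean_phase=mean_phase[(slice(None),) + sl],
        amplitudes=amp[(slice(None), slice(None)) + sl],
        params=params,
    )
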