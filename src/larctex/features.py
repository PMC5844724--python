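"""First-order and histogram texture features of a masked tumor slice.

The unit of analysis is a single 2D image slice with a binary region-of-
interest (ROI) mask drawn around the tumor. Seven features summarise the
distribution of in-ROI intensities while ignoring their spatial arrangement:

* **mean**, **standard deviation** — location and dispersion of the raw
  intensities (SD uses the unbiased 1/(N-1) form).
* **skewness**, **kurtosis** — standardised third and fourth central moments
  of the raw intensities, with population (1/N) moments. Kurtosis is
  *non-excess*: a Gaussian ROI gives kurtosis ≈ 3.
* **uniformity**, **entropy** — computed on a discretized histogram of the
  ROI intensities (equally spaced bins spanning the in-ROI range).
  Uniformity is Σ P(i)²; entropy is −Σ P(i) log₂ P(i) in bits.
* **energy** — mean of the squared min-max-normalised intensities,
  (1/N) Σ x̃(i)² with x̃ ∈ [0, 1] within the ROI, so that the value is
  bounded in [0, 1] and comparable across patients.

Discretization ("resampling into equally spaced bins") reduces noise and
normalises intensity scales across patients before the histogram features
are computed; the bin count is configurable (default 32) and is recorded in
every output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaskedImage",
    "DiscretizedHistogram",
    "TextureFeatures",
    "FEATURE_NAMES",
    "discretize",
    "compute_first_order",
    "compute_histogram_features",
    "extract_features",
]

#: Canonical order of the seven texture parameters.
FEATURE_NAMES = ("mean", "sd", "skewness", "kurtosis", "uniformity", "energy", "entropy")

#: Default number of equally spaced intensity bins.
DEFAULT_N_BINS = 32


@dataclass(frozen=True)
class MaskedImage:
    """One 2D tumor slice plus a binary ROI mask and acquisition metadata.

    Parameters
    ----------
    pixels : 2D float array
        Intensity values in arbitrary T2-weighted signal units.
    mask : 2D bool array
        Same shape as ``pixels``; True marks in-ROI pixels. Must select at
        least one pixel, and the selected intensities must be finite.
    patient_id, timepoint, rater
        Identifiers; ``timepoint`` is ``"pre"`` or ``"early"``.
    """

    pixels: np.ndarray
    mask: np.ndarray
    patient_id: str = ""
    timepoint: str = "pre"
    rater: str = ""

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {pixels.shape}")
        if mask.shape != pixels.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match pixel shape {pixels.shape}"
            )
        if not mask.any():
            raise ValueError("empty ROI: mask selects no pixels")
        if not np.isfinite(pixels[mask]).all():
            raise ValueError("masked intensities must be finite")
        object.__setattr__(self, "pixels", pixels)
        object.__setattr__(self, "mask", mask)

    @property
    def intensities(self) -> np.ndarray:
        """The in-ROI intensity values as a flat array."""
        return self.pixels[self.mask]


@dataclass(frozen=True)
class DiscretizedHistogram:
    """Equally spaced intensity histogram of an ROI.

    ``bin_edges`` has length ``n_bins + 1`` and is strictly increasing;
    ``counts`` sums to the ROI pixel count and ``probabilities`` to 1.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    probabilities: np.ndarray
    n_bins: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=np.int64)
        probs = np.asarray(self.probabilities, dtype=float)
        if len(counts) != self.n_bins or len(edges) != self.n_bins + 1:
            raise ValueError("inconsistent histogram sizes")
        if not (np.diff(edges) > 0).all():
            raise ValueError("bin edges must be strictly increasing")
        if (counts < 0).any():
            raise ValueError("negative bin count")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "probabilities", probs)

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class TextureFeatures:
    """The seven first-order/histogram features for one masked image."""

    mean: float
    sd: float
    skewness: float
    kurtosis: float
    uniformity: float
    energy: float
    entropy: float
    n_bins_used: int
    n_pixels: int

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def discretize(values, n_bins: int = DEFAULT_N_BINS) -> DiscretizedHistogram:
    """Resample intensities into ``n_bins`` equally spaced bins.

    Bins span ``[min(values), max(values)]``; a value falls into bin
    ``floor((x - min) / width)``, with the maximum clipped into the last
    (right-closed) bin. A zero intensity range puts all mass in a single
    bin so that constant ROIs flow through the pipeline.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty ROI")
    if not np.isfinite(values).all():
        raise ValueError("intensities must be finite")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo, hi = values.min(), values.max()
    counts = np.zeros(n_bins, dtype=np.int64)
    if hi == lo:
        # Degenerate range: single occupied bin, unit-width placeholder edges.
        edges = lo + np.arange(n_bins + 1, dtype=float)
        counts[0] = values.size
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        width = (hi - lo) / n_bins
        idx = np.floor((values - lo) / width).astype(np.int64)
        np.clip(idx, 0, n_bins - 1, out=idx)
        counts = np.bincount(idx, minlength=n_bins)
    return DiscretizedHistogram(
        bin_edges=edges,
        counts=counts,
        probabilities=counts / values.size,
        n_bins=n_bins,
    )


def compute_first_order(values) -> tuple[float, float, float, float]:
    """Mean, SD, skewness and kurtosis of raw (undiscretized) intensities.

    SD uses the unbiased 1/(N−1) estimator; skewness and kurtosis use
    population (1/N) central moments in numerator and denominator
    (kurtosis non-excess, Gaussian ≈ 3). With zero variance the two shape
    statistics are undefined and returned as NaN with a warning; with a
    single pixel the SD is undefined as well.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty ROI")
    n = values.size
    mean = values.mean()
    centered = values - mean
    if n >= 2:
        sd = float(np.sqrt((centered**2).sum() / (n - 1)))
    else:
        warnings.warn("single-pixel ROI: sd undefined", RuntimeWarning, stacklevel=2)
        sd = float("nan")
    m2 = float((centered**2).mean())
    if m2 == 0.0 or not np.isfinite(sd) or n < 2:
        warnings.warn(
            "zero intensity variance: skewness and kurtosis undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        skew = kurt = float("nan")
        if n >= 2:
            sd = 0.0 if m2 == 0.0 else sd
    else:
        m3 = float((centered**3).mean())
        m4 = float((centered**4).mean())
        skew = m3 / m2**1.5
        kurt = m4 / m2**2
    return float(mean), sd, skew, kurt


def compute_histogram_features(
    hist: DiscretizedHistogram,
    intensities=None,
    *,
    uniformity_mode: str = "standard",
    energy_mode: str = "minmax",
) -> tuple[float, float, float]:
    """Uniformity, energy and entropy of a discretized histogram.

    Returns ``(uniformity, energy, entropy)``. Uniformity is Σ P(i)²
    (``uniformity_mode="printed"`` selects the index-weighted variant
    Σ i·P(i)² with 1-based bin index, kept for auditability only — it is
    not bounded by 1). Entropy is −Σ P log₂ P in bits with 0·log 0 := 0.

    Energy is the mean squared min-max-normalised intensity. When the raw
    ``intensities`` are supplied (the normal path, used by
    :func:`extract_features`) it is computed from them exactly; otherwise
    it is approximated from normalised bin centers weighted by P(i).
    ``energy_mode="printed"`` selects the raw sum Σ X(i)² (unbounded).
    A zero intensity range gives energy 1.0 by convention, matching the
    fully ordered histogram (uniformity 1, entropy 0).
    """
    p = hist.probabilities
    if uniformity_mode == "standard":
        uniformity = float((p**2).sum())
    elif uniformity_mode == "printed":
        uniformity = float((np.arange(1, hist.n_bins + 1) * p**2).sum())
    else:
        raise ValueError(f"unknown uniformity_mode {uniformity_mode!r}")

    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    # clamp the -0.0 that a single-bin histogram produces
    entropy = abs(entropy)

    if intensities is not None:
        x = np.asarray(intensities, dtype=float).ravel()
        lo, hi = x.min(), x.max()
        if energy_mode == "printed":
            energy = float((x**2).sum())
        elif energy_mode == "minmax":
            if hi == lo:
                energy = 1.0
            else:
                xt = (x - lo) / (hi - lo)
                energy = float((xt**2).mean())
        else:
            raise ValueError(f"unknown energy_mode {energy_mode!r}")
    else:
        centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
        lo, hi = hist.bin_edges[0], hist.bin_edges[-1]
        if energy_mode == "printed":
            energy = float((p * centers**2).sum() * hist.n_pixels)
        elif energy_mode == "minmax":
            ct = (centers - lo) / (hi - lo)
            energy = float((p * ct**2).sum())
        else:
            raise ValueError(f"unknown energy_mode {energy_mode!r}")
    return uniformity, energy, entropy


def extract_features(
    img: MaskedImage,
    n_bins: int = DEFAULT_N_BINS,
    *,
    uniformity_mode: str = "standard",
    energy_mode: str = "minmax",
) -> TextureFeatures:
    """Compute all seven texture features of a masked image.

    First-order statistics (mean, SD, skewness, kurtosis) and energy are
    computed on the raw in-ROI intensities; uniformity and entropy on the
    discretized histogram with ``n_bins`` equally spaced bins. The bin
    count and ROI pixel count are recorded in the result.
    """
    values = img.intensities
    mean, sd, skew, kurt = compute_first_order(values)
    hist = discretize(values, n_bins)
    uniformity, energy, entropy = compute_histogram_features(
        hist, values, uniformity_mode=uniformity_mode, energy_mode=energy_mode
    )
    return TextureFeatures(
        mean=mean,
        sd=sd,
        skewness=skew,
        kurtosis=kurt,
        uniformity=uniformity,
        energy=energy,
        entropy=entropy,
        n_bins_used=n_bins,
        n_pixels=values.size,
    )
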