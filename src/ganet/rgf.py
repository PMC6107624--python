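"""Relative graphlet frequency (RGF) distance and spectrum correlation.

For a graph *G* with graphlet counts N_i and total T(G) = Σ_i N_i, the
relative frequency profile is F_i(G) = −log(N_i(G)/T(G)) (natural log),
and the RGF distance between two graphs is the L1 distance

    D(G, H) = Σ_{i=1..29} |F_i(G) − F_i(H)|.

F_i is undefined at N_i = 0; a zero count is replaced by a pseudocount
(default 1, leaving T unchanged) symmetrically for both spectra, which
keeps D finite, nonnegative, symmetric and zero between identical
spectra.  Distances therefore form a pseudometric on spectra under a
fixed pseudocount convention; absolute values depend on that
convention and on the log base, so only distances computed with the
same settings are comparable.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .census import MotifSpectrum, N_GRAPHLET_CLASSES

logger = logging.getLogger("ganet")

__all__ = ["RGFProfile", "rgf_profile", "rgf_distance", "spectrum_correlation"]


class RGFProfile:
    """Negative-log relative graphlet frequencies F_i and total count T."""

    __slots__ = ("F", "T")

    def __init__(self, F: np.ndarray, T: int):
        self.F = np.asarray(F, dtype=float)
        self.T = int(T)

    def __repr__(self):
        return f"RGFProfile(T={self.T}, F={np.round(self.F, 3)!r})"


def _check_graphlet_spectrum(spec: MotifSpectrum) -> None:
    if spec.kind != "undirected-graphlet":
        raise TypeError("RGF is defined on undirected graphlet spectra")
    if len(spec.counts) != N_GRAPHLET_CLASSES:
        raise ValueError("graphlet spectrum must have 29 classes")


def rgf_profile(spectrum: MotifSpectrum, pseudocount: float = 1.0) -> RGFProfile:
    """F_i = −ln(max(N_i, pseudocount)/T); errors when T = 0."""
    _check_graphlet_spectrum(spectrum)
    T = spectrum.total
    if T <= 0:
        raise ValueError("RGF profile undefined: graph has no graphlets (T=0)")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    N = np.maximum(spectrum.counts.astype(float), pseudocount)
    return RGFProfile(F=-np.log(N / T), T=T)


def rgf_distance(g_spec: MotifSpectrum, h_spec: MotifSpectrum,
                 pseudocount: float = 1.0) -> float:
    """L1 distance between the RGF profiles of two spectra."""
    fg = rgf_profile(g_spec, pseudocount)
    fh = rgf_profile(h_spec, pseudocount)
    return float(np.abs(fg.F - fh.F).sum())


def spectrum_correlation(a: MotifSpectrum, b: MotifSpectrum) -> float:
    """Pearson correlation between two raw count spectra.

    Both spectra must have the same kind/length.  Returns NaN with a
    warning when either spectrum has zero variance.
    """
    if a.kind != b.kind:
        raise TypeError(f"cannot correlate {a.kind} with {b.kind}")
    x = a.counts.astype(float)
    y = b.counts.astype(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("spectrum correlation undefined: zero variance")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)
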