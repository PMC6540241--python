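"""Linear B-cell epitope profiling with propensity scales and the EIIP spectrum.

Candidate epitope regions of a protein are scored by several classic
per-residue propensity methods (sliding-window averages of published scales,
a windowed surface-probability product, and a windowed electron-ion
interaction potential profile) plus the informational spectrum method (ISM):
the Fourier amplitude spectrum of the mean-removed EIIP signal.  A simple
vote across z-normalised profiles then calls consensus regions.

The vote rule: each profile is z-scored and oriented so that higher means
more epitope-like; a residue "votes" for a profile when its normalised score
is positive; maximal runs of residues whose vote fraction reaches the
threshold, and that are long enough, become ranked epitope calls.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import _scales
from .genetic_code import validate_peptide

__all__ = [
    "ScalePolarity",
    "PropensityScale",
    "ResidueProfile",
    "EiipSpectrum",
    "CrossSpectrum",
    "EpitopeCall",
    "BUILTIN_SCALES",
    "windowed_profile",
    "eiip_spectrum",
    "cross_spectrum",
    "consensus_regions",
    "profile_suite",
]


class ScalePolarity(enum.Enum):
    HIGH_IS_EPITOPE = "high"
    LOW_IS_EPITOPE = "low"


@dataclass(frozen=True)
class PropensityScale:
    """A named per-residue scale with an epitope orientation.

    ``combine`` selects how window values aggregate: ``"mean"`` (arithmetic
    mean, the default) or ``"product"`` (running product, as in the Emini
    surface-probability method where each window value is additionally
    scaled by 0.37**window).
    """

    name: str
    values: Mapping[str, float]
    polarity: ScalePolarity = ScalePolarity.HIGH_IS_EPITOPE
    combine: str = "mean"

    def __post_init__(self) -> None:
        missing = sorted(set("ACDEFGHIKLMNPQRSTVWY") - set(self.values))
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {missing}")
        if self.combine not in ("mean", "product"):
            raise ValueError(f"unknown combine rule {self.combine!r}")


BUILTIN_SCALES: Mapping[str, PropensityScale] = {
    "kd": PropensityScale("kyte-doolittle", _scales.KYTE_DOOLITTLE,
                          ScalePolarity.LOW_IS_EPITOPE),
    "parker": PropensityScale("parker", _scales.PARKER,
                              ScalePolarity.HIGH_IS_EPITOPE),
    "emini": PropensityScale("emini", _scales.EMINI,
                             ScalePolarity.HIGH_IS_EPITOPE, combine="product"),
    "turn": PropensityScale("chou-fasman-turn", _scales.CHOU_FASMAN_TURN,
                            ScalePolarity.HIGH_IS_EPITOPE),
    "eiip": PropensityScale("eiip", _scales.EIIP,
                            ScalePolarity.HIGH_IS_EPITOPE),
}


@dataclass(frozen=True)
class ResidueProfile:
    """Per-residue scores of one method on one sequence."""

    sequence: str
    method: str
    scores: np.ndarray
    window: int
    polarity: ScalePolarity = ScalePolarity.HIGH_IS_EPITOPE

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (len(self.sequence),):
            raise ValueError("scores length must equal sequence length")
        object.__setattr__(self, "scores", scores)


def windowed_profile(seq: str, scale: PropensityScale, window: int = 9) -> ResidueProfile:
    """Sliding-window profile of a propensity scale over a sequence.

    The score at position i is the aggregate (mean or product, per the
    scale's ``combine`` rule) of scale values over the window centred at i.
    Positions whose window would overrun an end are edge-clamped to the
    nearest full-window value, so no truncated windows enter the profile.
    """
    seq = validate_peptide(seq)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    n = len(seq)
    if window > n:
        raise ValueError(f"window {window} exceeds sequence length {n}")
    vals = np.array([scale.values[r] for r in seq], dtype=float)
    half = window // 2
    centres = np.empty(n - window + 1)
    if scale.combine == "product":
        factor = 0.37 ** window
        for j in range(n - window + 1):
            centres[j] = factor * np.prod(vals[j : j + window])
    else:
        kernel = np.full(window, 1.0 / window)
        centres = np.convolve(vals, kernel, mode="valid")
    scores = np.concatenate([
        np.full(half, centres[0]),
        centres,
        np.full(half, centres[-1]),
    ])
    return ResidueProfile(sequence=seq, method=scale.name, scores=scores,
                          window=window, polarity=scale.polarity)


def profile_suite(seq: str, methods: Iterable[str] = ("kd", "parker", "emini", "turn", "eiip"),
                  window: int = 9) -> List[ResidueProfile]:
    """Run the built-in propensity methods on one sequence."""
    return [windowed_profile(seq, BUILTIN_SCALES[m], window) for m in methods]


@dataclass(frozen=True)
class EiipSpectrum:
    """One-sided amplitude spectrum of a mean-removed EIIP signal.

    Amplitudes carry a Parseval (unit-energy) normalisation: the sum of
    squared amplitudes equals the sum of squared mean-removed EIIP values.
    Frequencies lie on (0, 0.5] in cycles per residue; the zero-frequency
    (mean) component is removed before the transform.
    """

    sequence: str
    frequencies: np.ndarray
    amplitudes: np.ndarray
    signal: np.ndarray  # mean-removed EIIP values, kept for cross-spectra

    @property
    def peak_frequency(self) -> float:
        return float(self.frequencies[int(np.argmax(self.amplitudes))])


def _eiip_signal(seq: str) -> np.ndarray:
    vals = np.array([_scales.EIIP[r] for r in seq], dtype=float)
    return vals - vals.mean()


def _one_sided_amplitudes(signal: np.ndarray, n: int) -> Tuple[np.ndarray, np.ndarray]:
    spec = np.fft.rfft(signal, n=n)
    k = np.arange(1, spec.size)
    freqs = k / n
    weights = np.where((n % 2 == 0) & (k == n // 2), 1.0, 2.0)
    amps = np.abs(spec[1:]) * np.sqrt(weights / n)
    return freqs, amps


def eiip_spectrum(seq: str) -> EiipSpectrum:
    """Informational spectrum of a peptide: DFT amplitudes of its EIIP signal."""
    seq = validate_peptide(seq)
    if len(seq) < 4:
        raise ValueError(f"sequence too short for a spectrum (length {len(seq)} < 4)")
    signal = _eiip_signal(seq)
    freqs, amps = _one_sided_amplitudes(signal, len(signal))
    return EiipSpectrum(sequence=seq, frequencies=freqs, amplitudes=amps, signal=signal)


@dataclass(frozen=True)
class CrossSpectrum:
    """Element-wise amplitude product of two informational spectra."""

    frequencies: np.ndarray
    amplitudes: np.ndarray

    @property
    def peak_frequency(self) -> float:
        return float(self.frequencies[int(np.argmax(self.amplitudes))])


def cross_spectrum(a: EiipSpectrum, b: EiipSpectrum) -> CrossSpectrum:
    """Common-frequency analysis of two sequences.

    The shorter signal is zero-padded so both transforms share one frequency
    grid; the cross-spectrum is the element-wise product of amplitudes, whose
    peak marks a frequency component common to both sequences.
    """
    n = max(a.signal.size, b.signal.size)
    fa, aa = _one_sided_amplitudes(a.signal, n)
    _, ab = _one_sided_amplitudes(b.signal, n)
    return CrossSpectrum(frequencies=fa, amplitudes=aa * ab)


@dataclass(frozen=True)
class EpitopeCall:
    """A consensus epitope region, 1-based inclusive coordinates."""

    start: int
    end: int
    mean_vote: float
    mean_score: float
    sequence: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must not exceed end")


def _oriented_zscores(profile: ResidueProfile) -> Optional[np.ndarray]:
    s = profile.scores
    sd = s.std()
    if sd == 0:
        return None
    z = (s - s.mean()) / sd
    if profile.polarity is ScalePolarity.LOW_IS_EPITOPE:
        z = -z
    return z


def consensus_regions(
    profiles: Sequence[ResidueProfile],
    vote_threshold: float = 0.5,
    min_length: int = 5,
) -> List[EpitopeCall]:
    """Call consensus epitope regions from several residue profiles.

    Each profile is z-scored and oriented so higher = more epitope-like; a
    residue votes under a profile when its normalised score is positive.
    Maximal runs whose per-residue vote fraction is >= ``vote_threshold``
    and whose length is >= ``min_length`` are returned ranked by mean vote,
    then mean normalised score.  Constant profiles are skipped with a
    warning (they carry no vote information).
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles for a consensus")
    if not 0 < vote_threshold <= 1:
        raise ValueError("vote_threshold must lie in (0, 1]")
    seqs = {p.sequence for p in profiles}
    if len(seqs) != 1:
        raise ValueError("profiles computed on different sequences")
    sequence = profiles[0].sequence

    zs = []
    for p in profiles:
        z = _oriented_zscores(p)
        if z is None:
            warnings.warn(f"profile {p.method!r} is constant; skipped in consensus")
        else:
            zs.append(z)
    if len(zs) < 2:
        raise ValueError("fewer than two non-constant profiles; no consensus possible")
    Z = np.vstack(zs)
    votes = (Z > 0).mean(axis=0)
    mean_z = Z.mean(axis=0)

    calls: List[EpitopeCall] = []
    n = len(sequence)
    i = 0
    while i < n:
        if votes[i] >= vote_threshold:
            j = i
            while j + 1 < n and votes[j + 1] >= vote_threshold:
                j += 1
            if j - i + 1 >= min_length:
                calls.append(EpitopeCall(
                    start=i + 1, end=j + 1,
                    mean_vote=float(votes[i : j + 1].mean()),
                    mean_score=float(mean_z[i : j + 1].mean()),
                    sequence=sequence[i : j + 1],
                ))
            i = j + 1
        else:
            i += 1
    calls.sort(key=lambda c: (-c.mean_vote, -c.mean_score, c.start))
    return calls
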