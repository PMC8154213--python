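"""Molecular formulas, adduct m/z values, and natural-abundance isotopologue envelopes.

The screening readout works on narrow m/z windows, so the chemistry layer has
to answer two questions precisely: where does an ion of a given formula fall
on the m/z axis, and how much of its isotopologue envelope leaks into a
neighbouring detection channel.  The latter matters whenever a product ion
sits only two mass units above its substrate (e.g. an imine-to-amine
reduction): the substrate's M+2 isotopologue is then m/z-coincident with the
product channel and produces a false positive under every genuine hit.

Isotope masses and abundances are IUPAC 2021 representative values, embedded
below.  Only singly charged [M+H]+ / [M-H]- ions (and neutral masses) are
supported; that covers the small-molecule screening use case this package
targets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElementComposition",
    "AdductSpec",
    "IsotopeEnvelope",
    "parse_formula",
    "monoisotopic_mz",
    "isotope_envelope",
    "interference_fraction",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "SUPPORTED_ELEMENTS",
]

ELECTRON_MASS = 0.000548579909  # Da
# proton mass defined as m(1H) - m(e) for exact consistency with the
# atom-based isotope table below (agrees with CODATA to ~1.5e-8 Da)
PROTON_MASS = 1.0078250319 - ELECTRON_MASS  # Da

# element -> [(isotope mass / Da, natural abundance fraction), ...],
# lightest isotope first.  IUPAC 2021 representative values.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.0078250319, 0.999885), (2.0141017781, 0.000115)],
    "C": [(12.0, 0.9893), (13.0033548351, 0.0107)],
    "N": [(14.0030740044, 0.99636), (15.0001088989, 0.00364)],
    "O": [(15.9949146196, 0.99757), (16.9991317565, 0.00038), (17.9991596129, 0.00205)],
    "F": [(18.9984031627, 1.0)],
    "P": [(30.9737619984, 1.0)],
    "S": [(31.9720711744, 0.9499), (32.9714589098, 0.0075), (33.9678670040, 0.0425), (35.9670807, 0.0001)],
    "Cl": [(34.968852682, 0.7576), (36.965902602, 0.2424)],
    "Br": [(78.9183376, 0.5069), (80.9162897, 0.4931)],
}

SUPPORTED_ELEMENTS = frozenset(ISOTOPES)

# peak merge tolerance within an envelope (Da); far below the 0.2 Da channel
# window used downstream, so merged isotopologues never straddle a channel edge
MERGE_TOL = 0.01


@dataclass(frozen=True)
class ElementComposition:
    """Element -> count map for a neutral molecular formula.

    Counts are non-negative integers over the supported element set; at least
    one count must be positive.
    """

    counts: dict[str, int]

    def __post_init__(self) -> None:
        for el, n in self.counts.items():
            if el not in SUPPORTED_ELEMENTS:
                raise ValueError(f"unsupported element symbol: {el!r}")
            if not isinstance(n, (int, np.integer)) or n < 0:
                raise ValueError(f"element count must be a non-negative integer: {el}={n!r}")
        if not any(n > 0 for n in self.counts.values()):
            raise ValueError("composition must contain at least one atom")

    def __add__(self, other: "ElementComposition") -> "ElementComposition":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementComposition(merged)

    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def hill_formula(self) -> str:
        """Canonical Hill-order formula string (C, H, then alphabetical)."""
        items = {el: n for el, n in self.counts.items() if n > 0}
        order: list[str] = []
        if "C" in items:
            order.append("C")
            if "H" in items:
                order.append("H")
            order.extend(sorted(el for el in items if el not in ("C", "H")))
        else:
            order.extend(sorted(items))
        return "".join(f"{el}{items[el] if items[el] != 1 else ''}" for el in order)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill_formula()


@dataclass(frozen=True)
class AdductSpec:
    """Ionization adduct: protonated [M+H]+, deprotonated [M-H]-, or neutral M."""

    kind: str  # "[M+H]+", "[M-H]-", or "M"
    polarity: int = field(init=False)

    _POLARITY = {"[M+H]+": 1, "[M-H]-": -1, "M": 0}

    def __post_init__(self) -> None:
        if self.kind not in self._POLARITY:
            raise ValueError(f"unknown adduct kind: {self.kind!r}")
        object.__setattr__(self, "polarity", self._POLARITY[self.kind])

    @classmethod
    def protonated(cls) -> "AdductSpec":
        return cls("[M+H]+")

    @classmethod
    def deprotonated(cls) -> "AdductSpec":
        return cls("[M-H]-")

    @classmethod
    def neutral(cls) -> "AdductSpec":
        return cls("M")

    @classmethod
    def parse(cls, text: str) -> "AdductSpec":
        t = text.strip()
        aliases = {
            "[M+H]+": "[M+H]+", "M+H": "[M+H]+", "+H": "[M+H]+",
            "[M-H]-": "[M-H]-", "M-H": "[M-H]-", "-H": "[M-H]-",
            "M": "M", "neutral": "M",
        }
        if t not in aliases:
            raise ValueError(f"unknown adduct: {text!r}")
        return cls(aliases[t])


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Centroided isotopologue envelope: ordered (mass, abundance) peaks.

    Abundances are fractions summing to 1 (renormalized after truncation);
    ``nominal_offsets`` labels each peak with its integer M+k offset from the
    monoisotopic peak.
    """

    masses: np.ndarray  # Da, strictly increasing
    abundances: np.ndarray  # fractions, sum to 1
    nominal_offsets: np.ndarray  # int M+k labels

    def __post_init__(self) -> None:
        m = np.asarray(self.masses, dtype=float)
        a = np.asarray(self.abundances, dtype=float)
        if m.size == 0:
            raise ValueError("envelope must contain at least one peak")
        if np.any(np.diff(m) <= 0):
            raise ValueError("envelope masses must be strictly increasing")
        if abs(a.sum() - 1.0) > 1e-9:
            raise ValueError("envelope abundances must sum to 1")

    @property
    def base_peak_abundance(self) -> float:
        return float(np.max(self.abundances))

    def __len__(self) -> int:
        return int(self.masses.size)


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementComposition:
    """Parse an element-count formula string like ``"C12H15NO2"``.

    Hill order is not required on input; the canonical output order is Hill
    (see :meth:`ElementComposition.hill_formula`).  Unknown element symbols
    and empty strings are rejected.
    """
    if not isinstance(text, str) or not text.strip():
        raise ValueError("empty formula string")
    s = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _FORMULA_TOKEN.match(s, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in SUPPORTED_ELEMENTS:
            raise ValueError(f"unknown element symbol {el!r} in formula {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ElementComposition(counts)


def _ion_composition(comp: ElementComposition, adduct: AdductSpec) -> ElementComposition:
    """Atom inventory of the ion (adds/removes the transferred hydrogen)."""
    counts = dict(comp.counts)
    if adduct.polarity == 1:
        counts["H"] = counts.get("H", 0) + 1
    elif adduct.polarity == -1:
        if counts.get("H", 0) < 1:
            raise ValueError("cannot deprotonate a composition without hydrogen")
        counts["H"] = counts["H"] - 1
    return ElementComposition(counts)


def monoisotopic_mz(comp: ElementComposition, adduct: AdductSpec) -> float:
    """Monoisotopic m/z of a singly charged ion (or neutral monoisotopic mass).

    For ions the electron mass is accounted for, so
    ``mz([M+H]+) - mz([M-H]-) == 2 * PROTON_MASS`` exactly.
    """
    ion = _ion_composition(comp, adduct) if adduct.polarity != 0 else comp
    mass = sum(ISOTOPES[el][0][0] * n for el, n in ion.counts.items())
    if adduct.polarity == 1:
        return mass - ELECTRON_MASS
    if adduct.polarity == -1:
        return mass + ELECTRON_MASS
    return mass


def _merge_peaks(masses: np.ndarray, abund: np.ndarray, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate peaks closer than ``tol``; merged mass is abundance-weighted."""
    order = np.argsort(masses, kind="stable")
    masses, abund = masses[order], abund[order]
    out_m: list[float] = []
    out_a: list[float] = []
    for m, a in zip(masses, abund):
        if out_m and m - out_m[-1] <= tol:
            tot = out_a[-1] + a
            out_m[-1] = (out_m[-1] * out_a[-1] + m * a) / tot
            out_a[-1] = tot
        else:
            out_m.append(float(m))
            out_a.append(float(a))
    return np.array(out_m), np.array(out_a)


def _convolve(a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray],
              prune: float) -> tuple[np.ndarray, np.ndarray]:
    ma, aa = a
    mb, ab = b
    masses = (ma[:, None] + mb[None, :]).ravel()
    abund = (aa[:, None] * ab[None, :]).ravel()
    masses, abund = _merge_peaks(masses, abund, MERGE_TOL)
    keep = abund > prune
    if not np.any(keep):
        keep = abund == abund.max()
    return masses[keep], abund[keep]


def _element_distribution(el: str, n: int, prune: float) -> tuple[np.ndarray, np.ndarray]:
    """Isotopologue distribution of n atoms of one element, by binary convolution."""
    iso = ISOTOPES[el]
    base = (np.array([m for m, _ in iso]), np.array([p for _, p in iso]))
    result: tuple[np.ndarray, np.ndarray] | None = None
    power = base
    k = n
    while k > 0:
        if k & 1:
            result = power if result is None else _convolve(result, power, prune)
        k >>= 1
        if k:
            power = _convolve(power, power, prune)
    assert result is not None
    return result


def isotope_envelope(comp: ElementComposition, adduct: AdductSpec,
                     truncation: float = 1e-6) -> IsotopeEnvelope:
    """Natural-abundance isotopologue envelope of an ion (or neutral molecule).

    The envelope is the convolution of per-element multinomial isotopologue
    distributions, with peaks closer than 0.01 Da aggregated, truncated at
    ``truncation`` of total abundance and renormalized.  For ionic adducts the
    transferred hydrogen is included in the atom inventory and the electron
    mass is applied to the m/z axis.

    Parameters
    ----------
    truncation:
        Relative abundance below which peaks are dropped, in (0, 0.01].
    """
    if not (0 < truncation <= 0.01):
        raise ValueError("truncation must lie in (0, 0.01]")
    ion = _ion_composition(comp, adduct) if adduct.polarity != 0 else comp
    # intermediate pruning far below the final truncation: the 0.01 Da merge
    # already bounds peak-list growth, so pruning only sheds float dust
    prune = 1e-15
    dist: tuple[np.ndarray, np.ndarray] | None = None
    for el, n in sorted(ion.counts.items()):
        if n == 0:
            continue
        d = _element_distribution(el, n, prune)
        dist = d if dist is None else _convolve(dist, d, prune)
    assert dist is not None
    masses, abund = dist
    keep = abund >= truncation * abund.sum()
    masses, abund = masses[keep], abund[keep]
    abund = abund / abund.sum()
    if adduct.polarity == 1:
        masses = masses - ELECTRON_MASS
    elif adduct.polarity == -1:
        masses = masses + ELECTRON_MASS
    mono = monoisotopic_mz(comp, adduct)
    offsets = np.rint(masses - mono).astype(int)
    return IsotopeEnvelope(masses=masses, abundances=abund, nominal_offsets=offsets)


def interference_fraction(envelope: IsotopeEnvelope, target_mz: float, window: float) -> float:
    """Fraction of an envelope falling inside an m/z window, relative to its base peak.

    This is the leakage a coincident detection channel at ``target_mz`` picks
    up from a species whose base-peak intensity is measured elsewhere: sum the
    abundances with mass in ``[target - window/2, target + window/2)`` and
    divide by the base-peak abundance.  The result is 0 when no peak falls in
    the window and >= 1 when the base peak itself does.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if len(envelope) == 0:  # defensive; the dataclass already forbids this
        raise ValueError("empty envelope")
    lo, hi = target_mz - window / 2.0, target_mz + window / 2.0
    inside = (envelope.masses >= lo) & (envelope.masses < hi)
    return float(envelope.abundances[inside].sum() / envelope.base_peak_abundance)


def envelope_fraction_in_window(envelope: IsotopeEnvelope, target_mz: float,
                                window: float) -> float:
    """Absolute fraction of an ion's envelope captured by an m/z window.

    Unlike :func:`interference_fraction` this is normalized to the whole
    envelope, not the base peak: it is the factor by which a narrow channel
    undercounts a species' total ion signal (a 0.2 Da window around the
    monoisotopic peak captures only the M+0 isotopologue).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    lo, hi = target_mz - window / 2.0, target_mz + window / 2.0
    inside = (envelope.masses >= lo) & (envelope.masses < hi)
    return float(envelope.abundances[inside].sum())
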