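"""Load-class schemes for categorical pollen forecasts.

A classification scheme maps a daily pollen concentration (pollen grains per
cubic meter of air) to an ordered set of load classes, e.g.
``no < low < moderate < high``.  Plain classes are half-open concentration
bands ``[lower, upper)`` that jointly cover ``[0, inf)``, so every
non-negative concentration belongs to exactly one plain class.  The printed
presentation of such schemes ("0-0.99", "1-19.9", "20-49.9", "50 and above")
leaves gaps between bands; the half-open convention closes them while
agreeing with every printed bound.

Some forecast providers additionally issue *intermediate* classes that
bridge two adjacent plain classes (e.g. "low-moderate").  Each intermediate
class carries a numeric overlap interval centred on the boundary between its
pair: with boundary centre ``c`` and interval fraction ``f`` (default 20%)
the interval is ``[c*(1-f), c*(1+f)]``.  The centre is taken as the upper
class's lower bound minus 0.5, i.e. the midpoint between that bound and the
last printed value of the lower class at one-decimal resolution (19.5 for
low/moderate, 49.5 for moderate/high under the default scheme).  A pair may
instead be configured with a literal band; the default scheme's no-low band
(0-2) is such a literal, since no +/-20% construction produces it.

Verification against a forecast label uses :func:`is_hit`: a forecast is
correct when the observed concentration lies in the (optionally
tolerance-expanded) band of the forecast class, where the tolerance widens
the band symmetrically by ``t`` pollen/m3 at both ends, floored at zero.
With the overlap rule enabled, a plain-class forecast adjacent to an
intermediate interval is also correct when the observation falls in that
interval — the counting rule under which an observation in the overlap
region credits both neighbouring categories.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import InputError

__all__ = [
    "PLAIN",
    "INTERMEDIATE",
    "LoadClass",
    "ClassificationScheme",
    "default_scheme",
    "classify",
    "classify_many",
    "build_intermediate_interval",
    "expand_band",
    "is_hit",
]

PLAIN = "plain"
INTERMEDIATE = "intermediate"


@dataclass(frozen=True)
class LoadClass:
    """One labelled concentration band.

    Parameters
    ----------
    label : str
        Category name, unique within a scheme.
    lower : float
        Inclusive lower bound in pollen/m3, >= 0.
    upper : float or None
        Exclusive upper bound for plain classes, inclusive for intermediate
        ones; ``None`` means unbounded above.
    kind : {"plain", "intermediate"}
    """

    label: str
    lower: float
    upper: float | None
    kind: str = PLAIN

    def __post_init__(self):
        if not math.isfinite(self.lower) or self.lower < 0:
            raise InputError(
                f"class {self.label!r}: lower bound must be finite and >= 0, "
                f"got {self.lower}")
        if self.upper is not None:
            if not math.isfinite(self.upper) or not self.lower < self.upper:
                raise InputError(
                    f"class {self.label!r}: need lower < upper, got "
                    f"[{self.lower}, {self.upper}]")
        if self.kind not in (PLAIN, INTERMEDIATE):
            raise InputError(f"class {self.label!r}: unknown kind {self.kind!r}")

    def contains(self, conc: float, tolerance: float = 0.0) -> bool:
        """Whether ``conc`` lies in this band widened by ``tolerance``.

        Plain bands are half-open on the right; intermediate bands are
        closed (their printed endpoints belong to the interval).
        """
        lo, hi = expand_band(self, tolerance)
        if self.kind == PLAIN:
            return lo <= conc < hi
        return lo <= conc <= hi


@dataclass(frozen=True)
class ClassificationScheme:
    """An ordered, exhaustive set of plain load classes plus optional
    intermediate overlap classes.

    Plain classes must tile ``[0, inf)`` contiguously under the half-open
    convention.  Each intermediate class must straddle exactly one boundary
    between adjacent plain classes.
    """

    plain_classes: tuple[LoadClass, ...]
    intermediate_classes: tuple[LoadClass, ...] = ()
    interval_fraction: float = 0.2
    name: str = "scheme"

    def __post_init__(self):
        plain = tuple(self.plain_classes)
        inter = tuple(self.intermediate_classes)
        object.__setattr__(self, "plain_classes", plain)
        object.__setattr__(self, "intermediate_classes", inter)
        if not plain:
            raise InputError("scheme needs at least one plain class")
        if not 0 < self.interval_fraction < 1:
            raise InputError("interval_fraction must lie in (0, 1)")
        if any(c.kind != PLAIN for c in plain):
            raise InputError("plain_classes must all have kind 'plain'")
        if any(c.kind != INTERMEDIATE for c in inter):
            raise InputError(
                "intermediate_classes must all have kind 'intermediate'")
        if plain[0].lower != 0:
            raise InputError("lowest plain class must start at 0")
        for a, b in zip(plain, plain[1:]):
            if a.upper is None or a.upper != b.lower:
                raise InputError(
                    f"plain classes {a.label!r} and {b.label!r} must be "
                    "contiguous (upper of one == lower of next)")
        if plain[-1].upper is not None:
            raise InputError("highest plain class must be unbounded above")
        labels = [c.label for c in plain + inter]
        if len(set(labels)) != len(labels):
            raise InputError("class labels must be unique")
        # map each intermediate to the unique plain boundary it straddles
        pair_of: dict[str, tuple[str, str]] = {}
        by_pair: dict[tuple[str, str], LoadClass] = {}
        boundaries = [(a.label, b.label, a.upper) for a, b in zip(plain, plain[1:])]
        for ic in inter:
            hits = [(lo, hi) for lo, hi, b in boundaries
                    if ic.lower <= b <= (ic.upper if ic.upper is not None else math.inf)]
            if len(hits) != 1:
                raise InputError(
                    f"intermediate class {ic.label!r} must straddle exactly "
                    f"one plain boundary, straddles {len(hits)}")
            if hits[0] in by_pair:
                raise InputError(
                    f"two intermediate classes bridge the pair {hits[0]}")
            pair_of[ic.label] = hits[0]
            by_pair[hits[0]] = ic
        object.__setattr__(self, "_pair_of", pair_of)
        object.__setattr__(self, "_by_pair", by_pair)
        object.__setattr__(
            self, "_by_label", {c.label: c for c in plain + inter})

    # -- lookups -----------------------------------------------------------

    @property
    def labels(self) -> tuple[str, ...]:
        """All labels, plain first in band order, then intermediates."""
        return tuple(c.label for c in self.plain_classes + self.intermediate_classes)

    @property
    def plain_labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.plain_classes)

    def class_for(self, label: str) -> LoadClass:
        try:
            return self._by_label[label]
        except KeyError:
            raise InputError(
                f"unknown label {label!r} for scheme {self.name!r}; "
                f"known labels: {', '.join(self.labels)}") from None

    def pair_for(self, intermediate_label: str) -> tuple[str, str]:
        """The (lower, upper) plain pair an intermediate class bridges."""
        cls = self.class_for(intermediate_label)
        if cls.kind != INTERMEDIATE:
            raise InputError(f"{intermediate_label!r} is not intermediate")
        return self._pair_of[intermediate_label]

    def intermediate_for_pair(self, lower_label: str,
                              upper_label: str) -> LoadClass | None:
        return self._by_pair.get((lower_label, upper_label))

    def intermediates_adjacent_to(self, plain_label: str) -> tuple[LoadClass, ...]:
        """Intermediate classes whose pair includes ``plain_label``."""
        return tuple(ic for ic in self.intermediate_classes
                     if plain_label in self._pair_of[ic.label])

    def ordinal_code(self, label: str) -> float:
        """Position of a label on the ordinal scale 0..k-1.

        Plain labels get integer codes in band order; an intermediate label
        sits at the midpoint of its pair's codes.
        """
        cls = self.class_for(label)
        if cls.kind == PLAIN:
            return float(self.plain_labels.index(label))
        lo, hi = self._pair_of[label]
        return (self.plain_labels.index(lo) + self.plain_labels.index(hi)) / 2.0

    # -- (de)serialisation -------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "ClassificationScheme":
        """Build a scheme from its JSON configuration structure.

        Intermediate entries without an explicit ``band`` get the
        fraction-interval construction around their pair's boundary centre.
        """
        frac = float(d.get("interval_fraction", 0.2))
        plain = tuple(
            LoadClass(e["label"],
                      float(e["lower"]),
                      None if e.get("upper") is None else float(e["upper"]),
                      PLAIN)
            for e in d["plain_classes"])
        # a bare scheme with only plain classes so the formula can run
        base = cls(plain, (), frac, d.get("name", "scheme"))
        inter = []
        for e in d.get("intermediate_classes", ()):
            pair = tuple(e["pair"])
            if "band" in e and e["band"] is not None:
                lo, hi = (float(x) for x in e["band"])
            else:
                lo, hi = build_intermediate_interval(pair[0], pair[1], base)
            inter.append(LoadClass(e["label"], lo, hi, INTERMEDIATE))
        return cls(plain, tuple(inter), frac, d.get("name", "scheme"))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "interval_fraction": self.interval_fraction,
            "plain_classes": [
                {"label": c.label, "lower": c.lower, "upper": c.upper}
                for c in self.plain_classes],
            "intermediate_classes": [
                {"label": c.label, "pair": list(self._pair_of[c.label]),
                 "band": [c.lower, c.upper]}
                for c in self.intermediate_classes],
        }


def default_scheme() -> ClassificationScheme:
    """The packaged four-class scheme (no/low/moderate/high) with the three
    intermediate overlap classes used by interval-style forecast providers."""
    text = (resources.files("pollenverify") / "data" / "default_scheme.json"
            ).read_text(encoding="utf-8")
    return ClassificationScheme.from_dict(json.loads(text))


def classify(conc: float, scheme: ClassificationScheme) -> str:
    """Map one concentration (pollen/m3) to its plain class label."""
    if not math.isfinite(conc) or conc < 0:
        raise InputError(f"concentration must be finite and >= 0, got {conc}")
    for c in reversed(scheme.plain_classes):
        if conc >= c.lower:
            return c.label
    raise AssertionError("unreachable: plain classes cover [0, inf)")


def classify_many(concs, scheme: ClassificationScheme) -> np.ndarray:
    """Vectorised :func:`classify` returning an array of labels."""
    arr = np.asarray(concs, dtype=float)
    if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr < 0)):
        raise InputError("concentrations must be finite and >= 0")
    lowers = np.array([c.lower for c in scheme.plain_classes])
    idx = np.searchsorted(lowers, arr, side="right") - 1
    return np.asarray(scheme.plain_labels, dtype=object)[idx]


def build_intermediate_interval(lower_label: str, upper_label: str,
                                scheme: ClassificationScheme
                                ) -> tuple[float, float]:
    """Overlap interval for an adjacent pair of plain classes.

    Returns the configured literal band when the scheme defines one for the
    pair; otherwise applies the fraction-interval construction
    ``[c*(1-f), c*(1+f)]`` with ``c`` the pair's boundary centre (the upper
    class's lower bound minus 0.5) and ``f`` the scheme's interval fraction.
    """
    plain = scheme.plain_labels
    try:
        i = plain.index(lower_label)
    except ValueError:
        raise InputError(f"unknown plain label {lower_label!r}") from None
    if i + 1 >= len(plain) or plain[i + 1] != upper_label:
        raise InputError(
            f"labels {lower_label!r} and {upper_label!r} are not adjacent "
            f"plain classes (order: {', '.join(plain)})")
    c = scheme.class_for(upper_label).lower - 0.5
    f = scheme.interval_fraction
    # round away binary float noise (19.5*0.8 = 15.600000000000001) so the
    # published one-decimal bands are reproduced exactly
    formula = (round(c * (1.0 - f), 9), round(c * (1.0 + f), 9))
    configured = scheme.intermediate_for_pair(lower_label, upper_label)
    if configured is not None and configured.upper is not None:
        stored = (configured.lower, configured.upper)
        # a configured band that deviates from the formula is a literal
        if not (math.isclose(stored[0], formula[0], abs_tol=1e-9)
                and math.isclose(stored[1], formula[1], abs_tol=1e-9)):
            return stored
    return formula


def expand_band(cls: LoadClass, tolerance: float) -> tuple[float, float]:
    """Widen a class band symmetrically by ``tolerance`` pollen/m3.

    The lower end is floored at 0; an unbounded upper end stays unbounded
    (returned as ``inf``).
    """
    if not math.isfinite(tolerance) or tolerance < 0:
        raise InputError(f"tolerance must be finite and >= 0, got {tolerance}")
    lo = max(0.0, cls.lower - tolerance)
    hi = math.inf if cls.upper is None else cls.upper + tolerance
    return lo, hi


def is_hit(forecast_label: str, observed: float, tolerance: float,
           scheme: ClassificationScheme, overlap_rule: bool = True) -> bool:
    """Whether a categorical forecast verifies against an observation.

    True when ``observed`` falls in the tolerance-expanded band of the
    forecast class.  With ``overlap_rule`` on, a plain forecast adjacent to
    an intermediate interval also verifies when the observation lies in that
    (equally expanded) interval; an intermediate forecast verifies exactly
    when the observation lies in its own expanded interval.
    """
    if not math.isfinite(observed) or observed < 0:
        raise InputError(f"observed concentration must be >= 0, got {observed}")
    cls = scheme.class_for(forecast_label)
    if cls.kind == INTERMEDIATE:
        return cls.contains(observed, tolerance)
    if cls.contains(observed, tolerance):
        return True
    if overlap_rule:
        for ic in scheme.intermediates_adjacent_to(forecast_label):
            if ic.contains(observed, tolerance):
                return True
    return False
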