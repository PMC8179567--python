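"""Ramachandran bins spanning both chiral halves of the torsion torus.

Classification uses a disjoint, mirror-symmetric four-bin partition:

* ``A`` (helical, φ<0), ``B`` (extended, φ<0) on the L side;
* ``a``, ``b`` — their exact sign-negated mirrors on the D side.

Two broader sampling-only regions, ``G`` and ``E`` (positive-φ turn and
extended regions), plus their left-half mirrors ``g``/``e``, may additionally
be drawn from during backbone sampling at reduced weight; they overlap the
four classification bins and are never returned by :func:`bin_of`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError
from .geometry import wrap_angle

Interval = tuple[float, float]  # half-open [lo, hi) on the circle, degrees


def _wrap_intervals(lo: float, hi: float) -> tuple[Interval, ...]:
    """Split a possibly wrapping half-open interval into (−180, 180] pieces."""
    lo = wrap_angle(lo) if lo != -180.0 else -180.0
    span = (hi - lo) % 360.0 or 360.0
    hi = lo + span
    if hi <= 180.0:
        return ((lo, hi),)
    return ((lo, 180.0), (-180.0, hi - 360.0))


def _mirror_intervals(ivs: tuple[Interval, ...]) -> tuple[Interval, ...]:
    out = []
    for lo, hi in ivs:
        out.extend(_wrap_intervals(-hi, -lo))
    return tuple(out)


@dataclass(frozen=True)
class RamaBin:
    """One φ/ψ region with a sampling weight.

    ``sampling_only`` marks the broad E/G-family regions that overlap the
    four-bin classification partition.
    """

    label: str
    phi_intervals: tuple[Interval, ...]
    psi_intervals: tuple[Interval, ...]
    weight: float = 1.0
    sampling_only: bool = False

    @property
    def chirality(self) -> str:
        lo, hi = self.phi_intervals[0]
        return "L" if (lo + hi) / 2.0 < 0 else "D"

    def contains(self, phi: float, psi: float) -> bool:
        phi = wrap_angle(phi)
        psi = wrap_angle(psi)
        return _in(phi, self.phi_intervals) and _in(psi, self.psi_intervals)

    def sample(self, rng: np.random.Generator) -> tuple[float, float]:
        return (_sample_intervals(self.phi_intervals, rng),
                _sample_intervals(self.psi_intervals, rng))

    def mirrored(self, label: str | None = None) -> "RamaBin":
        lab = label if label is not None else self.label.swapcase()
        return RamaBin(lab, _mirror_intervals(self.phi_intervals),
                       _mirror_intervals(self.psi_intervals), self.weight,
                       self.sampling_only)


def _in(x: float, ivs: tuple[Interval, ...]) -> bool:
    # half-open [lo, hi); 180 belongs to an interval ending at 180
    return any(lo <= x < hi or (x == 180.0 and hi == 180.0 and lo < 180.0)
               for lo, hi in ivs)


def _sample_intervals(ivs: tuple[Interval, ...], rng: np.random.Generator) -> float:
    lengths = np.array([hi - lo for lo, hi in ivs])
    i = int(rng.choice(len(ivs), p=lengths / lengths.sum())) if len(ivs) > 1 else 0
    lo, hi = ivs[i]
    return float(rng.uniform(lo, hi))


def default_bins(include_sampling_regions: bool = True,
                 broad_weight: float = 0.5) -> list[RamaBin]:
    """The default weighted bin set.

    A/B and their mirrors a/b carry weight 1; the broad positive-φ G/E
    regions and their mirrors g/e carry ``broad_weight`` and are flagged
    sampling-only.
    """
    A = RamaBin("A", _wrap_intervals(-180, 0), _wrap_intervals(-75, 50), 1.0)
    B = RamaBin("B", _wrap_intervals(-180, 0), _wrap_intervals(50, 285), 1.0)
    bins = [A, B, A.mirrored("a"), B.mirrored("b")]
    if include_sampling_regions:
        G = RamaBin("G", _wrap_intervals(0, 180), _wrap_intervals(-100, 100),
                    broad_weight, sampling_only=True)
        E = RamaBin("E", _wrap_intervals(0, 180), _wrap_intervals(100, 260),
                    broad_weight, sampling_only=True)
        bins += [G, E, G.mirrored("g"), E.mirrored("e")]
    return bins


def classification_bins(bins: list[RamaBin]) -> list[RamaBin]:
    return [b for b in bins if not b.sampling_only]


def bins_for_chirality(bins: list[RamaBin], chirality: str) -> list[RamaBin]:
    """Sub-set of a bin list on one side of the plot (L: φ<0, D: φ>0)."""
    return [b for b in bins if b.chirality == chirality]


def sample_phi_psi(bins: list[RamaBin], rng: np.random.Generator) -> tuple[float, float]:
    """Draw (φ, ψ) from a weighted bin set: bin ∝ weight, uniform within."""
    weights = np.array([b.weight for b in bins], float)
    if len(bins) == 0 or not np.any(weights > 0):
        raise ConfigurationError("no bin with positive sampling weight")
    p = weights / weights.sum()
    i = int(rng.choice(len(bins), p=p))
    return bins[i].sample(rng)


def bin_of(phi: float, psi: float, bins: list[RamaBin] | None = None) -> str:
    """Unique classification label for (φ, ψ).

    Mirror symmetry holds exactly: ``bin_of(−φ, −ψ) == bin_of(φ, ψ).swapcase()``
    for φ ≠ 0 (the positive-φ half classifies via the sign-negated point;
    φ = 0 falls to the L side by the documented tie-break).
    """
    cls = classification_bins(bins) if bins is not None else \
        classification_bins(default_bins())
    phi = wrap_angle(phi)
    psi = wrap_angle(psi)
    if phi == 180.0:
        phi = -180.0
    if phi > 0:
        return bin_of(-phi, -psi, bins).swapcase()
    l_bins = [b for b in cls if b.chirality == "L"]
    hits = [b.label for b in l_bins if b.contains(phi, psi)]
    if len(hits) != 1:
        # ψ boundary between two L bins: take the lexicographically first
        hits = sorted(hits) or [sorted(b.label for b in l_bins)[0]]
    return hits[0]


def bin_weight(phi: float, psi: float, bins: list[RamaBin] | None = None) -> float:
    """Sampling weight of the classification bin containing (φ, ψ),
    normalized by the maximum classification-bin weight (for the scoring
    term −log w)."""
    all_bins = bins if bins is not None else default_bins()
    cls = classification_bins(all_bins)
    wmax = max(b.weight for b in cls)
    for b in cls:
        if b.contains(phi, psi):
            return b.weight / wmax
    return 0.0


def assign_chirality(phi: float) -> str:
    """The φ-sign chirality rule: φ<0 → L, φ>0 → D, φ=0 → L (tie-break)."""
    return "D" if wrap_angle(phi) > 0 else "L"


# -- TOML (de)serialization -------------------------------------------------


def bins_to_dict(bins: list[RamaBin]) -> list[dict]:
    return [
        {
            "label": b.label,
            "phi": [list(iv) for iv in b.phi_intervals],
            "psi": [list(iv) for iv in b.psi_intervals],
            "weight": b.weight,
            "sampling_only": b.sampling_only,
        }
        for b in bins
    ]


def bins_from_dict(entries: list[dict]) -> list[RamaBin]:
    out = []
    for e in entries:
        out.append(RamaBin(
            e["label"],
            tuple(tuple(iv) for iv in e["phi"]),
            tuple(tuple(iv) for iv in e["psi"]),
            float(e.get("weight", 1.0)),
            bool(e.get("sampling_only", False)),
        ))
    return out
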