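"""Helical lattice arithmetic.

Connects the quantities that describe a 1-start helical filament: the rise
(axial translation per subunit, Å), the twist (azimuthal rotation per
subunit, degrees), the pitch (axial length of one full turn), the number of
subunits per turn, the exact helical repeat (u subunits in t turns, u and t
coprime) and the Bessel selection rule ``l = t*n + u*m`` that restricts
which Bessel orders n may contribute to layer line l of the filament's
diffraction pattern.

All arithmetic is pure and exact to floating-point precision; rounding to
the precision used in printed tables (rise to 2 decimals, twist to 1) is a
display concern, handled by :func:`rounded`.

Power spectra cannot determine the hand of a helix, so twist is stored as a
positive angle together with a ``handedness`` flag that defaults to
right-handed (+1) purely as a convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple
import warnings


@dataclass(frozen=True)
class HelicalSymmetry:
    """Rise/twist pair defining the 1-start helix of a filament.

    Parameters
    ----------
    rise : float
        Axial translation between consecutive subunits, Å. Must be > 0.
    twist : float
        Azimuthal rotation between consecutive subunits, degrees, in
        (0, 360].
    handedness : int
        +1 for a right-handed helix (default), -1 for left-handed. A sign
        convention only; amplitude spectra cannot measure it.
    """

    rise: float
    twist: float
    handedness: int = +1

    def __post_init__(self) -> None:
        if not (self.rise > 0 and math.isfinite(self.rise)):
            raise ValueError(f"rise must be positive and finite, got {self.rise}")
        if not (0 < self.twist <= 360):
            raise ValueError(f"twist must lie in (0, 360] degrees, got {self.twist}")
        if self.handedness not in (+1, -1):
            raise ValueError(f"handedness must be +1 or -1, got {self.handedness}")

    @property
    def pitch(self) -> float:
        """Axial length of one full helical turn, Å (= rise * 360 / twist)."""
        return self.rise * 360.0 / self.twist

    @property
    def units_per_turn(self) -> float:
        """Number of subunits per helical turn (= 360 / twist)."""
        return 360.0 / self.twist

    @property
    def signed_twist(self) -> float:
        """Twist with the handedness sign applied, degrees."""
        return self.handedness * self.twist


@dataclass(frozen=True)
class LatticeEstimate:
    """Pitch and subunits-per-turn, the pair read off a power spectrum."""

    pitch: float
    units_per_turn: float

    def __post_init__(self) -> None:
        if not (self.pitch > 0 and math.isfinite(self.pitch)):
            raise ValueError(f"pitch must be positive and finite, got {self.pitch}")
        if not (self.units_per_turn > 1 and math.isfinite(self.units_per_turn)):
            raise ValueError(
                f"units_per_turn must be > 1, got {self.units_per_turn}"
            )


@dataclass(frozen=True)
class RepeatSolution:
    """Exact helical repeat: u subunits in t turns with gcd(u, t) = 1."""

    subunits: int
    turns: int

    def __post_init__(self) -> None:
        if self.subunits < 1 or self.turns < 1:
            raise ValueError("subunits and turns must be positive integers")
        if math.gcd(self.subunits, self.turns) != 1:
            raise ValueError(
                f"repeat ({self.subunits}, {self.turns}) is not coprime"
            )

    @property
    def units_per_turn(self) -> float:
        return self.subunits / self.turns

    def repeat_length(self, rise: float) -> float:
        """Axial length of one exact repeat (u * rise), Å."""
        return self.subunits * rise


@dataclass(frozen=True)
class LayerLine:
    """A detected axial reflection in a filament power spectrum."""

    axial_spacing: float
    index_l: Optional[int] = None
    bessel_order: Optional[int] = None
    is_meridional: bool = False
    amplitude: float = float("nan")

    def __post_init__(self) -> None:
        if not self.axial_spacing > 0:
            raise ValueError("axial_spacing must be positive")


def symmetry_from_lattice(
    lattice: LatticeEstimate, handedness: int = +1
) -> HelicalSymmetry:
    """Convert a (pitch, units-per-turn) estimate to rise and twist.

    rise = pitch / units_per_turn, twist = 360 / units_per_turn. Full
    precision is retained; use :func:`rounded` for table-precision values.
    """
    return HelicalSymmetry(
        rise=lattice.pitch / lattice.units_per_turn,
        twist=360.0 / lattice.units_per_turn,
        handedness=handedness,
    )


def lattice_from_symmetry(sym: HelicalSymmetry) -> LatticeEstimate:
    """Inverse of :func:`symmetry_from_lattice`."""
    return LatticeEstimate(pitch=sym.pitch, units_per_turn=sym.units_per_turn)


def rounded(sym: HelicalSymmetry, rise_dp: int = 2, twist_dp: int = 1) -> HelicalSymmetry:
    """Copy of *sym* rounded to printed-table precision (display only)."""
    return replace(sym, rise=round(sym.rise, rise_dp), twist=round(sym.twist, twist_dp))


def units_per_turn_from_spacings(meridional_spacing: float, pitch_spacing: float) -> float:
    """Subunits per turn from the meridional (rise) and order-1 (pitch) spacings.

    The meridional reflection sits at 1/rise and the order-1 layer line at
    1/pitch, so their spacing ratio is the number of subunits per turn.
    """
    if meridional_spacing <= 0 or pitch_spacing <= 0:
        raise ValueError("spacings must be positive")
    if pitch_spacing < meridional_spacing:
        warnings.warn(
            "pitch spacing smaller than meridional spacing: the order-1 layer "
            "line cannot lie beyond the meridional reflection",
            stacklevel=2,
        )
    return pitch_spacing / meridional_spacing


def best_rational_repeat(units_per_turn: float, max_turns: int = 20) -> RepeatSolution:
    """Best coprime rational approximation u/t to the subunits per turn.

    Scans every denominator t = 1..max_turns, reduces u/t to lowest terms
    and keeps the fraction minimising ``|u/t - units_per_turn|``; ties go to
    the smaller number of turns.
    """
    if units_per_turn <= 1:
        raise ValueError("units_per_turn must be > 1")
    if max_turns < 1:
        raise ValueError("max_turns must be >= 1")
    best: Optional[Tuple[float, int, int]] = None
    for t in range(1, max_turns + 1):
        for u in (math.floor(units_per_turn * t), math.ceil(units_per_turn * t)):
            if u < 1:
                continue
            g = math.gcd(u, t)
            u_r, t_r = u // g, t // g
            err = abs(u_r / t_r - units_per_turn)
            key = (err, t_r, u_r)
            if best is None or key < best:
                best = key
    assert best is not None
    return RepeatSolution(subunits=best[2], turns=best[1])


def allowed_bessel_orders(
    index_l: int, repeat: RepeatSolution, max_abs_m: int = 3
) -> List[int]:
    """Bessel orders n allowed on layer line l by the selection rule.

    Solves ``l = t*n + u*m`` for integer n over |m| <= max_abs_m; returns
    the orders sorted by |n| (lowest order dominates at the resolved radii).
    """
    if max_abs_m < 0:
        raise ValueError("max_abs_m must be >= 0")
    u, t = repeat.subunits, repeat.turns
    orders = set()
    for m in range(-max_abs_m, max_abs_m + 1):
        num = index_l - u * m
        if num % t == 0:
            orders.add(num // t)
    return sorted(orders, key=lambda n: (abs(n), n))


def layer_line_spacing(index_l: int, repeat: RepeatSolution, rise: float) -> float:
    """Axial spacing (Å) of layer line l: (u * rise) / l."""
    if index_l < 1:
        raise ValueError("layer line index must be >= 1 (the equator has no axial spacing)")
    if rise <= 0:
        raise ValueError("rise must be positive")
    return repeat.repeat_length(rise) / index_l


def enumerate_symmetry_candidates(
    pitch: float, units_range: Tuple[float, float], step: float = 0.01
) -> List[LatticeEstimate]:
    """Grid of candidate lattices at fixed pitch.

    units_per_turn runs lo, lo+step, ... up to hi inclusive (within half a
    step of hi, so printed grids like 3.50..4.50 at 0.01 have 101 entries).
    """
    lo, hi = units_range
    if not (lo > 1):
        raise ValueError("units_per_turn lower bound must be > 1")
    if hi < lo:
        raise ValueError(f"empty units_per_turn range [{lo}, {hi}]")
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(math.floor((hi - lo) / step + 0.5)) + 1
    return [LatticeEstimate(pitch=pitch, units_per_turn=lo + i * step) for i in range(n)]


def asymmetric_units(n_segments: int, step_distance: float, rise: float) -> int:
    """Asymmetric units contributed by segments extracted every k rises.

    Segments boxed at an axial step of k * rise each contribute k unique
    subunits, so the count is n_segments * k with k = step/rise rounded.
    """
    if n_segments < 1 or step_distance <= 0 or rise <= 0:
        raise ValueError("all inputs must be positive")
    ratio = step_distance / rise
    k = round(ratio)
    if abs(ratio - k) > 0.01:
        raise ValueError(
            f"step/rise = {ratio:.4f} is not within 0.01 of an integer"
        )
    return n_segments * int(k)
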