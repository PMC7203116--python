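"""Inter- and intra-subunit interaction analysis on filament models.

Two subunits are "physical interaction partners" when at least
``min_atom_pairs`` heavy-atom pairs lie within ``interaction_cutoff`` Å of
each other (default 4.5 Å, a standard van-der-Waals contact criterion). A
salt bridge is an acidic group (Asp/Glu carboxylate oxygen or the
C-terminal carboxylate) within ``salt_bridge_cutoff`` Å (default 4.0) of a
basic group (Lys NZ, Arg guanidinium nitrogen, or the N-terminal amine).

The cutoffs are conventions, not measurements, and partner counts can shift
at other values — every result record therefore carries the settings used.
Neighbour searches use a k-d tree; a brute-force all-pairs check is kept as
the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .builder import FilamentModel, SubunitModel

ACIDIC_CLASSES = ("acidic", "c_terminus")
BASIC_CLASSES = ("basic", "n_terminus")


@dataclass(frozen=True)
class ContactSettings:
    """Distance criteria for contacts and salt bridges (Å)."""

    interaction_cutoff: float = 4.5
    salt_bridge_cutoff: float = 4.0
    min_atom_pairs: int = 1

    def __post_init__(self) -> None:
        if self.interaction_cutoff <= 0 or self.salt_bridge_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.min_atom_pairs < 1:
            raise ValueError("min_atom_pairs must be >= 1")


@dataclass
class InteractionMap:
    """Contact partners of one subunit, keyed by signed subunit offset."""

    center_index: int
    partners: Dict[int, int]  # offset -> number of atom pairs in contact
    settings: ContactSettings

    @property
    def offsets(self) -> List[int]:
        return sorted(self.partners)

    @property
    def partners_per_direction(self) -> int:
        """Number of interaction partners in one direction (positive offsets)."""
        return sum(1 for k in self.partners if k > 0)


@dataclass(frozen=True)
class SaltBridge:
    acidic: Tuple[str, int, int]  # residue_name, residue_seq, subunit index
    basic: Tuple[str, int, int]
    distance: float
    kind: Literal["intermolecular", "intramolecular"]

    @property
    def offset(self) -> int:
        return self.basic[2] - self.acidic[2]


def _contact_pair_count(
    coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float
) -> int:
    tree = cKDTree(coords_b)
    pairs = tree.query_ball_point(coords_a, r=cutoff)
    return int(sum(len(p) for p in pairs))


def interaction_partners(
    filament: FilamentModel,
    center: int,
    settings: ContactSettings = ContactSettings(),
    max_offset: Optional[int] = None,
) -> InteractionMap:
    """Contact partner map of subunit *center* against every other subunit.

    For the paper-style ±7 comparison the centre must have at least 7
    neighbours on each side; an explicit error names the required length.
    """
    n = filament.n_subunits
    if not 0 <= center < n:
        raise ValueError(f"center {center} outside filament of {n} subunits")
    if max_offset is not None:
        if center - max_offset < 0 or center + max_offset >= n:
            raise ValueError(
                f"center {center} needs {max_offset} subunits on each side; "
                f"the filament must contain at least {2 * max_offset + 1} subunits"
            )
    center_coords = filament.subunit_coords(center)
    partners: Dict[int, int] = {}
    for j in range(n):
        if j == center:
            continue
        offset = j - center
        if max_offset is not None and abs(offset) > max_offset:
            continue
        count = _contact_pair_count(
            center_coords, filament.subunit_coords(j), settings.interaction_cutoff
        )
        if count >= settings.min_atom_pairs:
            partners[offset] = count
    return InteractionMap(center_index=center, partners=partners, settings=settings)


def brute_force_partner_map(
    filament: FilamentModel,
    center: int,
    settings: ContactSettings = ContactSettings(),
) -> Dict[int, int]:
    """All-pairs distance oracle for interaction_partners (test use)."""
    center_coords = filament.subunit_coords(center)
    out: Dict[int, int] = {}
    for j in range(filament.n_subunits):
        if j == center:
            continue
        other = filament.subunit_coords(j)
        d = np.linalg.norm(center_coords[:, None, :] - other[None, :, :], axis=2)
        count = int(np.sum(d <= settings.interaction_cutoff))
        if count >= settings.min_atom_pairs:
            out[j - center] = count
    return out


def _charged_atoms(subunit: SubunitModel, classes: Tuple[str, ...]):
    return [
        (i, a) for i, a in enumerate(subunit.atoms) if a.charge_class in classes
    ]


def find_salt_bridges(
    filament: FilamentModel,
    settings: ContactSettings = ContactSettings(),
    scope: Literal["inter", "intra", "both"] = "both",
    center: Optional[int] = None,
) -> List[SaltBridge]:
    """Salt bridges involving subunit *center* (default: the middle subunit).

    Intermolecular bridges are reported modulo the helical symmetry: one
    representative per unique (acidic residue, basic residue, offset)
    triple, with the closest atom-pair distance. Intramolecular bridges are
    pairs within the centre subunit itself.
    """
    if scope not in ("inter", "intra", "both"):
        raise ValueError(f"unknown scope {scope!r}")
    n = filament.n_subunits
    if center is None:
        center = n // 2
    bridges: Dict[Tuple, SaltBridge] = {}
    acidic_by_sub = [_charged_atoms(s, ACIDIC_CLASSES) for s in filament.subunits]
    basic_by_sub = [_charged_atoms(s, BASIC_CLASSES) for s in filament.subunits]

    def consider(i_sub: int, j_sub: int) -> None:
        kind = "intramolecular" if i_sub == j_sub else "intermolecular"
        if scope == "inter" and kind == "intramolecular":
            return
        if scope == "intra" and kind == "intermolecular":
            return
        for _, aa in acidic_by_sub[i_sub]:
            for _, ba in basic_by_sub[j_sub]:
                if kind == "intramolecular" and aa.residue_seq == ba.residue_seq:
                    continue
                d = float(np.linalg.norm(aa.position - ba.position))
                if d > settings.salt_bridge_cutoff:
                    continue
                key = (
                    aa.residue_name,
                    aa.residue_seq,
                    ba.residue_name,
                    ba.residue_seq,
                    j_sub - i_sub,
                )
                prev = bridges.get(key)
                if prev is None or d < prev.distance:
                    bridges[key] = SaltBridge(
                        acidic=(aa.residue_name, aa.residue_seq, i_sub),
                        basic=(ba.residue_name, ba.residue_seq, j_sub),
                        distance=d,
                        kind=kind,
                    )

    for j in range(n):
        consider(center, j)
        if j != center:
            consider(j, center)
    return sorted(bridges.values(), key=lambda b: (b.kind, b.offset, b.distance))


@dataclass(frozen=True)
class NearestAcidic:
    subunit: int
    residue_name: Optional[str]
    residue_seq: Optional[int]
    distance: Optional[float]
    intramolecular: Optional[bool]


def nearest_acidic_to_nterm(filament: FilamentModel) -> List[NearestAcidic]:
    """Closest acidic group to each subunit's N-terminal amine nitrogen.

    Searches acidic side-chain/C-terminal oxygens of every subunit; reports
    per subunit the nearest group and whether it belongs to the same
    subunit. Subunits without an identifiable N-terminus are skipped;
    filaments with no acidic groups yield explicit "none" records.
    """
    acidic: List[Tuple[int, object]] = []
    for si, sub in enumerate(filament.subunits):
        for _, a in _charged_atoms(sub, ACIDIC_CLASSES):
            acidic.append((si, a))
    results: List[NearestAcidic] = []
    for si, sub in enumerate(filament.subunits):
        nterm = next(
            (a for a in sub.atoms if a.charge_class == "n_terminus"), None
        )
        if nterm is None:
            raise ValueError(f"subunit {si} has no identifiable N-terminal amine")
        if not acidic:
            results.append(NearestAcidic(si, None, None, None, None))
            continue
        best = min(
            acidic, key=lambda sa: np.linalg.norm(sa[1].position - nterm.position)
        )
        d = float(np.linalg.norm(best[1].position - nterm.position))
        results.append(
            NearestAcidic(
                subunit=si,
                residue_name=best[1].residue_name,
                residue_seq=best[1].residue_seq,
                distance=d,
                intramolecular=(best[0] == si),
            )
        )
    return results


_CHARGE_BY_LETTER = {"D": -1, "E": -1, "K": +1, "R": +1}
_VALID_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")


def net_formal_charge(sequence: str, termini: Literal["charged", "neutral"] = "charged") -> int:
    """Net formal charge of a sequence at neutral pH.

    Asp/Glu count -1, Lys/Arg +1, His 0; charged termini contribute +1 and
    -1 (cancelling in the net sum).
    """
    seq = sequence.upper()
    bad = [i + 1 for i, c in enumerate(seq) if c not in _VALID_LETTERS]
    if bad:
        raise ValueError(f"unknown residue letters at positions {bad}")
    charge = sum(_CHARGE_BY_LETTER.get(c, 0) for c in seq)
    if termini == "charged":
        charge += 1 - 1
    return charge
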