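"""Deterministic generators for every input the pipeline consumes.

Each generator is a pure function of its parameters (seed included) and
returns the generated object together with a :class:`GroundTruth` record
holding the full parameter set and the expected answers, so tests and the
acceptance pipeline can compare recovered values against construction
truth.

The toy subunit emulates what matters about a pilin monomer for this
pipeline: an elongated, internally asymmetric rigid body reaching a stated
maximal radius (35 Å for a 70 Å-wide filament), optionally decorated with
charged probe atoms. It does not emulate secondary structure, glycans or
real scattering contrast.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .builder import Atom, FilamentModel, SubunitModel, build_filament
from .curvature import FilamentTrace
from .diffraction import ProjectionImage, project_model
from .lattice import HelicalSymmetry


@dataclass
class GroundTruth:
    """Machine-readable record of generator settings and expected answers."""

    kind: str  # subunit | filament | image | traces
    parameters: Dict
    expected: Dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(kind=d["kind"], parameters=d["parameters"], expected=d["expected"])


@dataclass(frozen=True)
class ChargedProbe:
    """Request for an acidic/basic atom pair bridging a subunit offset.

    The acidic probe sits in the base subunit; the basic probe is placed so
    that, after symmetry expansion, the copy in the subunit *offset* steps
    up lies exactly *distance* Å away. offset 0 gives an intramolecular pair.
    """

    offset: int
    distance: float = 3.0
    acidic_residue: str = "GLU"
    basic_residue: str = "LYS"


def _rotation_z(deg: float) -> np.ndarray:
    t = math.radians(deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _self_symmetry_rmsd(coords: np.ndarray, max_fold: int = 6) -> float:
    """Smallest nearest-neighbour RMSD of the cloud to a z-rotated copy.

    Large values mean no internal rotational symmetry about z.
    """
    best = math.inf
    for fold in range(2, max_fold + 1):
        rot = _rotation_z(360.0 / fold)
        rotated = coords @ rot.T
        d = np.linalg.norm(rotated[:, None, :] - coords[None, :, :], axis=2)
        rmsd = float(np.sqrt(np.mean(np.min(d, axis=1) ** 2)))
        best = min(best, rmsd)
    return best


def make_toy_subunit(
    seed: int,
    n_atoms: int = 30,
    radial_extent: float = 35.0,
    axial_extent: float = 45.0,
    charged_probes: Sequence[ChargedProbe] = (),
    sym: Optional[HelicalSymmetry] = None,
) -> Tuple[SubunitModel, GroundTruth]:
    """Random elongated asymmetric point cloud standing in for a pilin.

    Atoms run from near the helical axis out to exactly *radial_extent*
    (so a built filament has diameter 2 * radial_extent), spread over
    *axial_extent* along z like the tilted N-terminal helix of a pilin.
    Charged probes need *sym* to place the bridging partner.
    """
    if n_atoms < 3:
        raise ValueError("n_atoms must be >= 3")
    if radial_extent <= 0:
        raise ValueError("radial_extent must be positive")
    if charged_probes and sym is None:
        raise ValueError("charged probes require the helical symmetry")
    rng = np.random.default_rng(seed)
    # Core cluster: a compact knot of atoms near the axis at a common z,
    # emulating the tightly packed N-terminal helix bundle. Its z-coherence
    # across subunits is what makes the meridional reflection visible.
    n_core = max(3, n_atoms // 4)
    core_r = rng.uniform(1.0, 4.0, size=n_core)
    core_a = rng.uniform(0.0, 2 * math.pi, size=n_core)
    core = np.column_stack(
        [
            core_r * np.cos(core_a),
            core_r * np.sin(core_a),
            rng.uniform(0.0, 1.5, size=n_core),
        ]
    )
    # Head path: radius grows out to radial_extent while z climbs, like the
    # tilted stalk and globular head of a pilin.
    n_head = n_atoms - n_core
    frac = np.linspace(0.0, 1.0, n_head)
    radius = 5.0 + (radial_extent - 5.0) * frac
    angle = 0.6 * frac + 0.15 * rng.standard_normal(n_head)
    z = axial_extent * frac + 0.8 * rng.standard_normal(n_head)
    jitter = rng.normal(scale=1.2, size=(n_head, 3))
    jitter[-1] = 0.0  # keep the outermost atom exactly at radial_extent
    head = np.column_stack(
        [radius * np.cos(angle), radius * np.sin(angle), z]
    ) + jitter
    head[-1, :2] *= radial_extent / np.linalg.norm(head[-1, :2])
    # jitter may push interior atoms past the stated extent; clip them back
    r_xy = np.linalg.norm(head[:, :2], axis=1)
    over = r_xy > radial_extent
    head[over, :2] *= (radial_extent / r_xy[over])[:, None]
    coords = np.vstack([core, head])
    atoms = [
        Atom(
            name="CA",
            element="C",
            residue_name="GLY",
            residue_seq=i + 1,
            position=coords[i],
        )
        for i in range(n_atoms)
    ]
    atoms[0].name = "N"
    atoms[0].element = "N"
    atoms[0].charge_class = "n_terminus"
    next_seq = n_atoms + 1
    probe_records = []
    for rank, probe in enumerate(charged_probes):
        acidic_pos, basic_pos = _probe_positions(
            probe, sym, rank, base_radius=radial_extent
        )
        atoms.append(
            Atom(
                name="OE1",
                element="O",
                residue_name=probe.acidic_residue,
                residue_seq=next_seq,
                position=acidic_pos,
                charge_class="acidic",
            )
        )
        atoms.append(
            Atom(
                name="NZ",
                element="N",
                residue_name=probe.basic_residue,
                residue_seq=next_seq + 1,
                position=basic_pos,
                charge_class="basic",
            )
        )
        probe_records.append(
            {
                "offset": probe.offset,
                "distance": probe.distance,
                "acidic": [probe.acidic_residue, next_seq],
                "basic": [probe.basic_residue, next_seq + 1],
            }
        )
        next_seq += 2
    sequence = "G" * n_atoms + "EK" * len(probe_records)
    subunit = SubunitModel(atoms=atoms, sequence=sequence, label=f"toy-{seed}")
    asym = _self_symmetry_rmsd(coords)
    if asym < 1.0:
        raise RuntimeError(
            f"generated cloud is unexpectedly self-similar (rmsd {asym:.2f})"
        )
    truth = GroundTruth(
        kind="subunit",
        parameters={
            "seed": seed,
            "n_atoms": n_atoms,
            "radial_extent": radial_extent,
            "axial_extent": axial_extent,
            "probes": probe_records,
        },
        expected={
            "diameter": 2.0 * max(
                radial_extent,
                float(np.max(np.linalg.norm(
                    [a.position[:2] for a in atoms], axis=1))),
            ),
            "self_symmetry_rmsd": asym,
            "salt_bridges": probe_records,
        },
    )
    return subunit, truth


# Probe lanes start outside the subunit body so engineered pairs cannot
# collide with body atoms; each probe gets its own radial ring.
_PROBE_BASE_RADIUS_PAD = 10.0
_PROBE_RING_SPACING = 10.0


def _probe_positions(
    probe: ChargedProbe, sym: Optional[HelicalSymmetry], rank: int,
    base_radius: float = 35.0,
) -> Tuple[np.ndarray, np.ndarray]:
    ring = base_radius + _PROBE_BASE_RADIUS_PAD + rank * _PROBE_RING_SPACING
    acidic = np.array([ring, 0.0, 0.7])
    if probe.offset == 0:
        basic = acidic + np.array([probe.distance, 0.0, 0.0])
        return acidic, basic
    assert sym is not None
    if sym.rise <= 4.5:
        raise ValueError(
            "rise must exceed contact range (4.5 Å) so probe images one rise "
            "apart cannot form spurious bridges"
        )
    rot = _rotation_z(sym.signed_twist * probe.offset)
    image = rot @ acidic + np.array([0.0, 0.0, sym.rise * probe.offset])
    # Basic probe of the base subunit sits `distance` radially outside where
    # the acidic probe's +offset image will land.
    direction = np.array([image[0], image[1], 0.0])
    direction /= np.linalg.norm(direction)
    basic = image + direction * probe.distance
    return acidic, basic


def make_contact_fixture(
    offsets: Sequence[int],
    sym: HelicalSymmetry,
    n: int = 17,
    contact_distance: float = 3.0,
    seed: int = 0,
) -> Tuple[FilamentModel, GroundTruth]:
    """Filament whose subunits touch exactly at the requested offsets.

    For each requested offset k a "lane" of two atoms is added on a
    dedicated radial ring: atom P and an atom Q placed where the k-step
    screw image of P lands, offset by *contact_distance*. After expansion,
    subunit i's Q is that distance from subunit (i+k)'s P and nothing else
    comes close, so the partner map of an interior subunit is exactly
    {±k for k in offsets}. Verified here by brute force; infeasible
    geometries (rise below the contact distance, offsets beyond the
    filament) raise.
    """
    offsets = sorted(set(int(k) for k in offsets))
    if any(k < 1 for k in offsets):
        raise ValueError("offsets must be positive integers")
    if offsets and offsets[-1] >= n // 2:
        raise ValueError(
            f"offset {offsets[-1]} needs a filament longer than {n} subunits"
        )
    if sym.rise <= 2.0 + contact_distance:
        raise ValueError("rise too small: lanes cannot be separated axially")
    atoms: List[Atom] = []
    # Minimal body near the axis; axial span kept small so body atoms of
    # neighbouring subunits stay farther apart than one rise.
    body = np.array([[1.5, 0.0, 0.0], [-0.8, 1.0, 0.8], [0.2, -1.2, 1.5]])
    for i, pos in enumerate(body):
        atoms.append(
            Atom(name="CA", element="C", residue_name="GLY",
                 residue_seq=i + 1, position=pos)
        )
    seq = len(body) + 1
    for rank, k in enumerate(offsets):
        ring = 25.0 + rank * _PROBE_RING_SPACING
        p = np.array([ring, 0.0, 0.7])
        rot = _rotation_z(sym.signed_twist * k)
        image = rot @ p + np.array([0.0, 0.0, sym.rise * k])
        direction = np.array([image[0], image[1], 0.0])
        direction /= np.linalg.norm(direction)
        q = image + direction * contact_distance
        atoms.append(Atom(name="P", element="C", residue_name="GLY",
                          residue_seq=seq, position=p))
        atoms.append(Atom(name="Q", element="C", residue_name="GLY",
                          residue_seq=seq + 1, position=q))
        seq += 2
    subunit = SubunitModel(
        atoms=atoms, sequence="G" * (seq - 1), label="contact-fixture"
    )
    filament = build_filament(subunit, sym, n)
    # Brute-force verification of the engineered contact pattern.
    from .contacts import ContactSettings, brute_force_partner_map

    center = n // 2
    settings = ContactSettings()
    got = sorted(brute_force_partner_map(filament, center, settings))
    want = sorted([k for k in offsets] + [-k for k in offsets])
    if got != want:
        raise RuntimeError(
            f"contact fixture verification failed: wanted offsets {want}, got {got}"
        )
    truth = GroundTruth(
        kind="filament",
        parameters={
            "offsets": offsets,
            "rise": sym.rise,
            "twist": sym.twist,
            "n": n,
            "contact_distance": contact_distance,
            "seed": seed,
        },
        expected={"partner_offsets": want,
                  "partners_per_direction": len(offsets)},
    )
    return filament, truth


def make_filament_image(
    sym: HelicalSymmetry,
    n_subunits: int = 48,
    noise_sigma: float = 0.0,
    seed: int = 0,
    pixel_size: float = 1.0,
    box: int = 512,
    subunit_seed: Optional[int] = None,
    radial_extent: float = 35.0,
    blur_sigma: float = 1.5,
) -> Tuple[ProjectionImage, GroundTruth]:
    """Noisy projection image of a toy filament with known symmetry.

    noise_sigma is expressed in units of the clean image's standard
    deviation, so SNR = 1 / noise_sigma (infinite at 0).
    """
    if subunit_seed is None:
        subunit_seed = seed
    subunit, _ = make_toy_subunit(
        subunit_seed, radial_extent=radial_extent
    )
    filament = build_filament(subunit, sym, n_subunits)
    image = project_model(
        filament, pixel_size=pixel_size, box=box, blur_sigma=blur_sigma
    )
    clean_std = float(image.grid.std())
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        image.grid = image.grid + rng.normal(
            scale=noise_sigma * clean_std, size=image.grid.shape
        )
    truth = GroundTruth(
        kind="image",
        parameters={
            "rise": sym.rise,
            "twist": sym.twist,
            "n_subunits": n_subunits,
            "noise_sigma": noise_sigma,
            "seed": seed,
            "subunit_seed": subunit_seed,
            "pixel_size": pixel_size,
            "box": box,
            "radial_extent": radial_extent,
            "blur_sigma": blur_sigma,
        },
        expected={
            "rise": sym.rise,
            "twist": sym.twist,
            "pitch": sym.pitch,
            "units_per_turn": sym.units_per_turn,
            "snr": math.inf if noise_sigma == 0 else 1.0 / noise_sigma,
        },
    )
    return image, truth


def make_trace_population(
    n: int,
    fraction_high: float,
    kappa_low: Tuple[float, float] = (0.2, 1.5),
    kappa_high: Tuple[float, float] = (2.5, 6.0),
    length_range: Tuple[float, float] = (1.0, 3.0),
    seed: int = 0,
    threshold: float = 2.0,
    point_spacing: float = 0.02,
    noise_sigma: float = 0.0,
    label: str = "unknown",
) -> Tuple[List[FilamentTrace], GroundTruth]:
    """Population of constant-curvature arc traces with a set mixture.

    Exactly round(n * fraction_high) traces get a curvature drawn above the
    threshold (from *kappa_high*), the rest below (from *kappa_low*), so at
    zero noise the classified fraction equals the requested one exactly.
    Lengths are in µm; *noise_sigma* adds Gaussian jitter to the points.
    """
    if not 0.0 <= fraction_high <= 1.0:
        raise ValueError("fraction_high must be in [0, 1]")
    if kappa_high[0] <= threshold:
        raise ValueError("kappa_high range must lie above the threshold")
    if kappa_low[1] >= threshold:
        raise ValueError("kappa_low range must lie below the threshold")
    rng = np.random.default_rng(seed)
    n_high = int(round(n * fraction_high))
    kappas = np.concatenate(
        [
            rng.uniform(*kappa_high, size=n_high),
            rng.uniform(*kappa_low, size=n - n_high),
        ]
    )
    order = rng.permutation(n)
    kappas = kappas[order]
    is_high = (np.arange(n) < n_high)[order]
    traces = []
    for i, kappa in enumerate(kappas):
        length = rng.uniform(*length_range)
        n_pts = max(int(length / point_spacing), 8)
        s = np.linspace(0.0, length, n_pts)
        radius = 1.0 / kappa
        phi = s * kappa
        pts = np.column_stack([radius * np.sin(phi), radius * (1 - np.cos(phi))])
        theta = rng.uniform(0, 2 * math.pi)
        pts = pts @ _rotation_z(math.degrees(theta))[:2, :2].T
        pts += rng.uniform(-5, 5, size=2)
        if noise_sigma > 0:
            pts = pts + rng.normal(scale=noise_sigma, size=pts.shape)
        traces.append(
            FilamentTrace(points=pts, label=label, trace_id=f"{label}{i:04d}")
        )
    truth = GroundTruth(
        kind="traces",
        parameters={
            "n": n,
            "fraction_high": fraction_high,
            "kappa_low": list(kappa_low),
            "kappa_high": list(kappa_high),
            "length_range": list(length_range),
            "seed": seed,
            "threshold": threshold,
            "point_spacing": point_spacing,
            "noise_sigma": noise_sigma,
            "label": label,
        },
        expected={
            "fraction_above_threshold": n_high / n,
            "kappa_per_trace": kappas.tolist(),
            "is_high": is_high.tolist(),
        },
    )
    return traces, truth
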