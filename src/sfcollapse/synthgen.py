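"""Synthetic structures, trajectories and recordings with known ground truth.

Every generator is driven by a single ``numpy.random.default_rng(seed)``
stream (PCG64) and emits a ground-truth sidecar next to its data, so that
downstream parameter-recovery tests never peek at internals.  The
geometry is idealized, not homology-modeled: a four-chain selectivity
filter stand-in with backbone N/CA/C/O for residues 624-628, a serine
stand-in at 620 (CB, OG) and an asparagine stand-in at 629 (CB, CG, OD1,
ND2), arranged with four-fold symmetry about z.  The collapsed reference
pinches the central carbonyl oxygens radially inward, so the difference
vector (the collapse coordinate) has an exactly known span.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .structio import AtomRecord, StructureModel, Trajectory, write_pdb

__all__ = [
    "make_reference_pair",
    "make_collapse_trajectory",
    "make_scan_ensemble",
    "make_hbond_toggle",
    "make_cavity_structure",
    "make_cavity_trajectory",
    "make_recordings",
    "ramp_plateau_path",
]

_CHAINS = ("A", "B", "C", "D")
_SF_RESIDUES = [(624, "SER"), (625, "VAL"), (626, "GLY"), (627, "PHE"), (628, "GLY")]
#: carbonyl oxygens displaced between the conductive and collapsed references
_PINCH_RESIDUES = (625, 626)


def _rot_z(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _template_chain(d_cb: float) -> list[tuple[int, str, str, str, np.ndarray]]:
    """One chain in its own frame (x = radially outward), as atom tuples."""
    atoms = []
    z = 0.0
    for resnum, resname in _SF_RESIDUES:
        atoms.append((resnum, resname, "N", "N", np.array([4.6, 0.8, z - 0.4])))
        atoms.append((resnum, resname, "CA", "C", np.array([5.0, 0.0, z])))
        atoms.append((resnum, resname, "C", "C", np.array([4.4, -0.6, z + 0.6])))
        # carbonyl O points inward, toward the pore axis
        atoms.append((resnum, resname, "O", "O", np.array([3.3, -0.7, z + 0.7])))
        z += 1.5
    # S620 stand-in on the pore helix, behind the filter
    atoms.append((620, "SER", "N", "N", np.array([8.6, 1.2, 0.2])))
    atoms.append((620, "SER", "CA", "C", np.array([9.0, 0.5, 0.8])))
    atoms.append((620, "SER", "C", "C", np.array([9.6, 1.1, 1.8])))
    atoms.append((620, "SER", "O", "O", np.array([10.4, 1.8, 1.6])))
    atoms.append((620, "SER", "CB", "C", np.array([8.0, 0.5, 1.0])))
    atoms.append((620, "SER", "OG", "O", np.array([7.4, -0.7, 1.0])))
    # N629 stand-in above the filter mouth; its CB sits exactly d_cb above
    # the S620 CB so the scan label equals the realized Cb-Cb distance
    cb = np.array([8.0, 0.5, 1.0 + d_cb])
    atoms.append((629, "ASN", "N", "N", cb + np.array([1.2, 0.9, 0.6])))
    atoms.append((629, "ASN", "CA", "C", cb + np.array([0.8, 0.0, 1.2])))
    atoms.append((629, "ASN", "C", "C", cb + np.array([1.6, -0.8, 1.8])))
    atoms.append((629, "ASN", "O", "O", cb + np.array([2.6, -1.2, 1.5])))
    atoms.append((629, "ASN", "CB", "C", cb))
    atoms.append((629, "ASN", "CG", "C", cb + np.array([-1.2, -0.5, -0.4])))
    atoms.append((629, "ASN", "OD1", "O", cb + np.array([-1.4, -1.7, -0.5])))
    atoms.append((629, "ASN", "ND2", "N", cb + np.array([-2.2, 0.4, -0.6])))
    return atoms


def _build_tetramer(d_cb: float) -> StructureModel:
    records = []
    for ci, chain in enumerate(_CHAINS):
        R = _rot_z(ci * math.pi / 2)
        for resnum, resname, name, element, pos in _template_chain(d_cb):
            records.append(AtomRecord(chain, resnum, resname, name, element, R @ pos))
    return StructureModel(records, list(_CHAINS))


def make_reference_pair(
    collapse_displacement: float = 1.0, d_cb: float = 10.0
) -> tuple[StructureModel, StructureModel, dict]:
    """Conductive and collapsed reference models of the idealized filter.

    The collapsed form moves the carbonyl oxygens of the two central filter
    residues radially inward by ``collapse_displacement`` (A) on every
    chain.  The two models share a coordinate frame and the four-fold
    symmetry makes the pinch free of net translation and rotation, so the
    true span of the difference vector is exactly
    ``collapse_displacement * sqrt(8)``.
    """
    ref_a = _build_tetramer(d_cb)
    coords = ref_a.coords.copy()
    moved = 0
    for i, a in enumerate(ref_a.atoms):
        if a.residue_number in _PINCH_RESIDUES and a.atom_name == "O":
            radial = coords[i].copy()
            radial[2] = 0.0
            coords[i] -= collapse_displacement * radial / np.linalg.norm(radial)
            moved += 1
    ref_b = ref_a.with_coords(coords)
    truth = {
        "span_A": collapse_displacement * math.sqrt(moved),
        "displaced_atoms": moved,
        "d_cb_A": d_cb,
    }
    return ref_a, ref_b, truth


def ramp_plateau_path(
    times_ps: np.ndarray, plateau: float, ramp_end_ps: float = 40_000.0
) -> np.ndarray:
    """Collapse path rising linearly from 0 to ``plateau`` by ``ramp_end_ps``."""
    t = np.asarray(times_ps, dtype=float)
    return plateau * np.clip(t / ramp_end_ps, 0.0, 1.0)


def make_collapse_trajectory(
    ref_a: StructureModel,
    ref_b: StructureModel,
    s_true: np.ndarray,
    dt_ps: float = 1000.0,
    noise_sigma: float = 0.3,
    seed: int = 0,
) -> tuple[Trajectory, pd.DataFrame]:
    """Trajectory interpolating A -> B along a programmed collapse path.

    ``frame(t) = A + s_true(t) * (B - A) + N(0, sigma^2)`` iid per
    coordinate on every atom.  Returns the trajectory and a ground-truth
    table (time_ps, s_true).
    """
    rng = np.random.default_rng(seed)
    s_true = np.asarray(s_true, dtype=float)
    xa, xb = ref_a.coords, ref_b.coords
    times = np.arange(len(s_true)) * dt_ps
    frames = (
        xa[None, :, :]
        + s_true[:, None, None] * (xb - xa)[None, :, :]
        + rng.normal(0.0, noise_sigma, size=(len(s_true), len(xa), 3))
    )
    truth = pd.DataFrame({"time_ps": times, "s_true": s_true})
    return Trajectory(ref_a, times, frames), truth


def default_scan_s_true(d: float) -> float:
    """Programmed plateau collapse for scan label d: s = (10 - d) / 5."""
    return (10.0 - d) / 5.0


def make_scan_ensemble(
    out_dir: str | Path,
    d_values=(5.0, 6.0, 7.0, 8.0, 9.0, 10.0),
    runs_per_d: int = 4,
    n_frames: int = 60,
    dt_ps: float = 1000.0,
    noise_sigma: float = 0.3,
    collapse_displacement: float = 1.0,
    ramp_end_ps: float = 40_000.0,
    s_true_of_d=default_scan_s_true,
    seed: int = 0,
) -> Path:
    """Write a full distance-scan ensemble plus manifest and truth sidecar.

    For each scan label d the Cb stand-ins of residues 620 and 629 are
    placed exactly d apart and ``runs_per_d`` independent noisy
    trajectories follow a ramp-plateau path to ``s_true_of_d(d)``.
    Returns the manifest path (YAML) consumable by ``scanpipe.run_scan``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    ref_a, ref_b, ref_truth = make_reference_pair(collapse_displacement, d_cb=10.0)
    write_pdb(ref_a, out_dir / "ref_conductive.pdb")
    write_pdb(ref_b, out_dir / "ref_collapsed.pdb")

    times = np.arange(n_frames) * dt_ps
    groups = []
    truth_rows = []
    for d in d_values:
        a_d, b_d, _ = make_reference_pair(collapse_displacement, d_cb=float(d))
        plateau = float(s_true_of_d(d))
        s_path = ramp_plateau_path(times, plateau, ramp_end_ps)
        paths = []
        for run in range(runs_per_d):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            traj, _ = make_collapse_trajectory(
                a_d, b_d, s_path, dt_ps, noise_sigma, seed=sub_seed
            )
            p = out_dir / f"traj_d{d:g}_run{run}.pdb"
            write_pdb(traj, p)
            paths.append(p.name)
            truth_rows.append(
                {"d_A": d, "run": run, "s_plateau_true": plateau, "seed": sub_seed}
            )
        groups.append({"d": float(d), "trajectories": paths})

    manifest = {
        "references": {
            "conductive": "ref_conductive.pdb",
            "collapsed": "ref_collapsed.pdb",
        },
        "selection": "resnum 624-628 and name N CA C O",
        "burn_in_ps": float(ramp_end_ps),
        "dt_ps": float(dt_ps),
        "distance_atoms": {"residue_a": 620, "name_a": "CB",
                           "residue_b": 629, "name_b": "CB"},
        "fit_window": [5.0, 11.0],
        "rmsf": {"measure": "resnum 624-627 and name O", "align": None},
        "hbond": {"focal_resnum": 629, "max_da_distance": 3.5,
                  "max_hda_angle": 30.0, "hydrogen_mode": "heavy"},
        "groups": groups,
    }
    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return manifest_path


def make_hbond_toggle(
    n_frames: int = 2000,
    inter_fraction: float = 0.3,
    dt_ps: float = 10.0,
    jitter: float = 0.05,
    seed: int = 0,
) -> tuple[Trajectory, pd.DataFrame]:
    """Trajectory whose N629 side chain toggles intra-/inter-subunit partners.

    Per frame and chain a seeded Bernoulli draw (shared across chains within
    a frame) decides whether the ND2 donor sits 2.9 A from its own chain's
    S620 OG (intra) or from the *next* chain's G628 backbone O (inter).  The
    CG antecedent is placed behind ND2 so the heavy-atom angle test passes,
    and OD1 is parked out of range of any acceptor.  Returns the trajectory
    and the per-frame truth labels.
    """
    rng = np.random.default_rng(seed)
    base = _build_tetramer(d_cb=8.0)
    coords0 = base.coords
    n_atoms = base.n_atoms
    next_chain = {c: _CHAINS[(i + 1) % 4] for i, c in enumerate(_CHAINS)}

    idx = {a.key: i for i, a in enumerate(base.atoms)}
    labels = rng.random(n_frames) < inter_fraction
    frames = np.repeat(coords0[None, :, :], n_frames, axis=0)
    frames += rng.normal(0.0, jitter, size=frames.shape)

    for f in range(n_frames):
        inter = bool(labels[f])
        for c in _CHAINS:
            if inter:
                acc = coords0[idx[(next_chain[c], 628, "O")]]
            else:
                acc = coords0[idx[(c, 620, "OG")]]
            # approach direction: mostly axial (+z) with a slight outward
            # tilt; keeps the donor clear of bystander acceptors
            up = np.array([0.0, 0.0, 1.0])
            radial = acc.copy()
            radial[2] = 0.0
            radial /= np.linalg.norm(radial)
            direction = 0.2 * radial + up
            direction /= np.linalg.norm(direction)
            nd2 = acc + 2.9 * direction
            cg = nd2 + 1.33 * direction  # antecedent directly behind the donor
            od1 = nd2 + 4.0 * direction  # parked out of range of donors
            cb = cg + 1.5 * direction
            for name, pos in (("ND2", nd2), ("CG", cg), ("OD1", od1), ("CB", cb)):
                frames[f, idx[(c, 629, name)]] = pos + rng.normal(0.0, jitter, 3)
    times = np.arange(n_frames) * dt_ps
    truth = pd.DataFrame(
        {"time_ps": times, "inter": labels.astype(int)}
    )
    return Trajectory(base, times, frames), truth


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.stack([r * np.cos(phi * i), r * np.sin(phi * i), z], axis=1)


def make_cavity_structure(
    cavity_radius: float = 4.6,
    probe_radius: float = 1.4,
    atom_vdw: float = 1.7,
    shell_point_spacing: float = 0.8,
    center=(0.0, 0.0, 0.0),
) -> tuple[StructureModel, dict]:
    """Closed spherical shell of carbon pseudo-atoms around an empty cavity.

    The shell sits at ``cavity_radius + atom_vdw + probe_radius`` so the
    probe-center accessible interior is analytically a sphere of radius
    ``cavity_radius`` (volume 4/3 pi r^3), up to shell discretization.
    """
    shell_r = cavity_radius + atom_vdw + probe_radius
    n = max(int(math.ceil(4 * math.pi * shell_r**2 / shell_point_spacing**2)), 16)
    pts = np.asarray(center, dtype=float) + shell_r * _fibonacci_sphere(n)
    atoms = [
        AtomRecord("S", i + 1, "SHL", "C", "C", p) for i, p in enumerate(pts)
    ]
    truth = {
        "cavity_radius_A": cavity_radius,
        "analytic_volume_A3": 4.0 / 3.0 * math.pi * cavity_radius**3,
        "shell_radius_A": shell_r,
        "n_atoms": n,
    }
    return StructureModel(atoms, ["S"]), truth


def make_cavity_trajectory(
    open_radius: float = 4.6,
    closed_radius: float = 1.2,
    n_frames: int = 10,
    probe_radius: float = 1.4,
    atom_vdw: float = 1.7,
    shell_point_spacing: float = 0.8,
) -> tuple[Trajectory, pd.DataFrame]:
    """Alternating open/closed cavity frames (even = open, odd = closed)."""
    open_model, open_truth = make_cavity_structure(
        open_radius, probe_radius, atom_vdw, shell_point_spacing
    )
    n = open_model.n_atoms
    unit = open_model.coords / open_truth["shell_radius_A"]
    closed_shell_r = closed_radius + atom_vdw + probe_radius
    frames = np.empty((n_frames, n, 3))
    rows = []
    for f in range(n_frames):
        open_f = f % 2 == 0
        r = open_truth["shell_radius_A"] if open_f else closed_shell_r
        frames[f] = unit * r
        cav = open_radius if open_f else closed_radius
        rows.append(
            {
                "frame": f,
                "open": int(open_f),
                "cavity_radius_A": cav,
                "analytic_volume_A3": 4.0 / 3.0 * math.pi * cav**3,
            }
        )
    times = np.arange(n_frames, dtype=float)
    return Trajectory(open_model, times, frames), pd.DataFrame(rows)


@dataclass
class RecordingTruth:
    """Programmed parameters of a synthetic voltage-clamp data set."""

    v_half_activation: float = -28.5  # mV
    k_activation: float = 7.41  # mV
    tau_deactivation_ms: float = 73.2
    v_half_inactivation: float = -18.8  # mV
    k_inactivation: float = 7.0  # mV
    tau_inactivation_ms: float = 50.0
    noise_sd: float = 0.0
    extras: dict = field(default_factory=dict)


def make_recordings(
    truth: RecordingTruth | None = None, seed: int = 0
) -> tuple[dict[str, pd.DataFrame], RecordingTruth]:
    """Synthetic two-electrode voltage-clamp data with known parameters.

    Returns a dict of tidy tables:

    * ``activation_iv`` — test potential (-90..+40 mV, 10 mV steps) vs
      normalized tail amplitude on a Boltzmann curve;
    * ``deactivation_trace`` — single-exponential tail decay (time_ms,
      current);
    * ``inactivation_trace`` — test-pulse decay exp(-t/tau_inact) whose
      100-ms steady-state ratio is exactly exp(-100/tau_inact);
    * ``ss_inactivation`` — steady-state inactivation ratio vs potential
      on a descending Boltzmann curve.
    """
    truth = truth or RecordingTruth()
    rng = np.random.default_rng(seed)
    sd = truth.noise_sd

    V = np.arange(-90.0, 41.0, 10.0)
    amp = 1.0 / (1.0 + np.exp((truth.v_half_activation - V) / truth.k_activation))
    activation = pd.DataFrame(
        {"V_mV": V, "amplitude": amp + rng.normal(0, sd, len(V))}
    )

    t = np.arange(0.0, 400.0, 0.5)
    deact = np.exp(-t / truth.tau_deactivation_ms)
    deactivation = pd.DataFrame(
        {"time_ms": t, "current": deact + rng.normal(0, sd, len(t))}
    )

    ti = np.arange(0.0, 150.0, 0.5)
    inact = np.exp(-ti / truth.tau_inactivation_ms)
    inactivation = pd.DataFrame(
        {"time_ms": ti, "current": inact + rng.normal(0, sd, len(ti))}
    )

    Vi = np.arange(-80.0, 41.0, 10.0)
    ratio = 1.0 / (1.0 + np.exp((Vi - truth.v_half_inactivation) / truth.k_inactivation))
    ss = pd.DataFrame({"V_mV": Vi, "ratio": ratio + rng.normal(0, sd, len(Vi))})

    tables = {
        "activation_iv": activation,
        "deactivation_trace": deactivation,
        "inactivation_trace": inactivation,
        "ss_inactivation": ss,
    }
    return tables, truth
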