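"""Synthetic annealing scenarios with known ground truth.

Real parch calculations need an MD engine to evaporate a water shell.
These generators emulate the observable consequences of that run —
per-residue water counts that decay as the temperature ramp passes each
residue's characteristic retention temperature — so every downstream
stage can be tested against a known retention order without dynamics.

The escape model is a logistic function of (T(t) - T_retention): a
convenient, smooth stand-in for the sharp but noisy evaporation seen in
real annealing, not a claim about water thermodynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .hydration_counter import CountParams, WaterCountSeries
from .structure_io import Atom, Frame, ProteinStructure, Residue
from .system_builder import AnnealingSchedule

__all__ = [
    "SyntheticScenario",
    "ToyTrajectory",
    "generate_count_series",
    "build_toy_structure",
    "generate_toy_trajectory",
    "reference_fixture",
]

#: logistic width of the evaporation transition, K
ESCAPE_WIDTH_K = 30.0


def _default_schedule() -> AnnealingSchedule:
    return AnnealingSchedule()


@dataclass
class SyntheticScenario:
    """Ground-truth description of a fake annealing run.

    retention_temps_K : per-residue temperature at which the residue's
        water departs (the ground truth recovery tests rank against).
    n_waters_per_residue : shell population per residue at the ramp start.
    noise : amplitude of additive bounded integer count noise (uniform in
        [-noise, +noise], clipped at zero) — the upward component is
        exactly what the monotonicity condition exists to remove.
    """

    n_residues: int = 20
    retention_temps_K: Optional[np.ndarray] = None
    n_waters_per_residue: int = 20
    schedule: AnnealingSchedule = field(default_factory=_default_schedule)
    noise: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.retention_temps_K is None:
            # evenly spread across the ramp, away from the endpoints
            lo = self.schedule.t_start_K + 50.0
            hi = self.schedule.t_end_K - 50.0
            self.retention_temps_K = np.linspace(lo, hi, self.n_residues)
        self.retention_temps_K = np.asarray(self.retention_temps_K, dtype=float)
        if self.retention_temps_K.size != self.n_residues:
            raise ValueError("retention_temps_K must have one entry per residue")
        fin = self.retention_temps_K[np.isfinite(self.retention_temps_K)]
        if fin.size and (np.any(fin < self.schedule.t_start_K)
                         or np.any(fin > self.schedule.t_end_K)):
            raise ValueError("finite retention temperatures must lie within the ramp")


def _survival_fraction(temps_K: np.ndarray, retention_K: float) -> np.ndarray:
    """Expected fraction of the initial shell still present at each T."""
    if np.isposinf(retention_K):
        return np.ones_like(temps_K)
    return 1.0 / (1.0 + np.exp((temps_K - retention_K) / ESCAPE_WIDTH_K))


def generate_count_series(scn: SyntheticScenario) -> tuple[WaterCountSeries, np.ndarray]:
    """Per-residue sigmoidal count decay plus bounded integer noise.

    Returns the series and the ground-truth retention temperatures (whose
    rank order the recovered parch values should reproduce).
    """
    times = scn.schedule.sample_times()
    temps = scn.schedule.temperature_at(times)
    rng = np.random.default_rng(scn.seed)
    counts = np.zeros((scn.n_residues, times.size), dtype=int)
    for i, t_ret in enumerate(scn.retention_temps_K):
        base = np.round(scn.n_waters_per_residue * _survival_fraction(temps, t_ret))
        if scn.noise:
            base = base + rng.integers(-scn.noise, scn.noise + 1, size=times.size)
        counts[i] = np.clip(base, 0, None).astype(int)
    series = WaterCountSeries(times_ps=times, counts=counts, temperatures_K=temps)
    return series, scn.retention_temps_K.copy()


def build_toy_structure(scn: SyntheticScenario, site_spacing: float = 1.5) -> ProteinStructure:
    """One-atom 'residues' on a line, spaced far beyond any counting cutoff.

    The wide spacing guarantees each water is within the cutoff of at most
    one residue, so the generator's survival ledger and the geometric
    water count coincide exactly.
    """
    atoms, residues = [], []
    for i in range(scn.n_residues):
        pos = np.array([site_spacing * (i + 1), site_spacing, site_spacing])
        atoms.append(Atom(i + 1, "CA", "C", i, pos))
        residues.append(Residue(i, "GLY", "A", i + 1, range(i, i + 1)))
    edge = site_spacing * (scn.n_residues + 1)
    return ProteinStructure(atoms=atoms, residues=residues,
                            box=np.array([edge, 3 * site_spacing, 3 * site_spacing]))


@dataclass
class ToyTrajectory:
    """A generated trajectory plus the generator's own occupancy ledger."""

    structure: ProteinStructure  # protein sites + water atoms
    frames: list[Frame]
    occupancy: np.ndarray  # (n_residues, n_frames) ground-truth counts


def generate_toy_trajectory(
    scn: SyntheticScenario,
    structure: Optional[ProteinStructure] = None,
    count_params: Optional[CountParams] = None,
) -> ToyTrajectory:
    """Emit coordinate frames of evaporating waters around fixed sites.

    Waters start inside the counting shell of their home residue. At each
    frame a surviving water escapes with probability given by the logistic
    of (T(t) - retention temperature); an escaped water teleports well
    beyond the cutoff and random-walks outward, never to return. Protein
    coordinates stay fixed (the annealing protocol position-restrains the
    protein). The returned ledger records, per residue per frame, how many
    of its waters had not escaped — which equals the geometric water count
    because residue sites are spaced beyond twice the cutoff.
    """
    params = count_params or CountParams(use_pbc=False)
    protein = structure or build_toy_structure(scn, site_spacing=max(1.5, 4 * params.d_water))
    rng = np.random.default_rng(scn.seed)
    times = scn.schedule.sample_times()
    temps = scn.schedule.temperature_at(times)
    n_res = scn.n_residues
    n_w = scn.n_waters_per_residue

    sites = np.array([
        protein.coordinates()[r.atom_span.start : r.atom_span.stop].mean(axis=0)
        for r in protein.protein_residues()
    ])
    if sites.shape[0] != n_res:
        raise ValueError("structure must supply one site per scenario residue")

    # assemble topology: protein atoms + one oxygen per water
    atoms = list(protein.atoms)
    residues = list(protein.residues)
    serial = max(a.serial for a in atoms)
    seq = max(r.seq_number for r in residues)
    home = np.repeat(np.arange(n_res), n_w)
    start_pos = np.zeros((n_res * n_w, 3))
    for w, res_i in enumerate(home):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = rng.uniform(0.4, 0.9) * params.d_water
        start_pos[w] = sites[res_i] + direction * radius
        serial += 1
        seq += 1
        a_idx = len(atoms)
        atoms.append(Atom(serial, "OW", "O", len(residues), start_pos[w]))
        residues.append(Residue(len(residues), "SOL", "A", seq,
                                range(a_idx, a_idx + 1), kind="water"))
    full = ProteinStructure(atoms=atoms, residues=residues, box=protein.box)

    protein_xyz = protein.coordinates()
    alive = np.ones(n_res * n_w, dtype=bool)
    # escape direction rises out of the plane of the residue sites (strong
    # +z component) so an escaped water walks away from EVERY site, never
    # through a neighbouring residue's shell
    angle = rng.uniform(0, 2 * np.pi, size=n_res * n_w)
    escape_dir = np.stack(
        [0.3 * np.cos(angle), 0.3 * np.sin(angle), np.ones_like(angle)], axis=1
    )
    escape_dir /= np.linalg.norm(escape_dir, axis=1, keepdims=True)
    escape_frame = np.full(n_res * n_w, -1, dtype=int)

    frames: list[Frame] = []
    occupancy = np.zeros((n_res, times.size), dtype=int)
    for f, (t, T) in enumerate(zip(times, temps)):
        if f > 0:
            # per-frame escape hazard so the survival curve tracks the logistic target
            surv_now = np.array([_survival_fraction(np.array([T]), scn.retention_temps_K[r])[0]
                                 for r in range(n_res)])
            surv_prev = np.array([_survival_fraction(np.array([temps[f - 1]]),
                                                     scn.retention_temps_K[r])[0]
                                  for r in range(n_res)])
            hazard = np.clip(1.0 - surv_now / np.maximum(surv_prev, 1e-12), 0.0, 1.0)
            u = rng.random(n_res * n_w)
            newly = alive & (u < hazard[home])
            alive &= ~newly
            escape_frame[newly] = f

        water_xyz = start_pos.copy()
        gone = ~alive
        if gone.any():
            age = f - escape_frame[gone]
            dist = 2.5 * params.d_water + 0.5 * params.d_water * age
            water_xyz[gone] = (sites[home[gone]]
                               + escape_dir[gone] * dist[:, None])
        coords = np.vstack([protein_xyz, water_xyz])
        frames.append(Frame(time_ps=float(t), coordinates=coords, box=protein.box))
        occupancy[:, f] = np.bincount(home[alive], minlength=n_res)

    return ToyTrajectory(structure=full, frames=frames, occupancy=occupancy)


def reference_fixture(
    schedule: Optional[AnnealingSchedule] = None,
    n_waters: int = 25,
) -> WaterCountSeries:
    """A single-residue maximal-retention series: the test-suite's 'lysine'.

    The count never drops over the whole ramp, so its normalized ACF is
    identically 1 and pointwise dominates any decaying residue's — the
    natural reference Cbar for synthetic scenarios.
    """
    schedule = schedule or AnnealingSchedule()
    times = schedule.sample_times()
    counts = np.full((1, times.size), n_waters, dtype=int)
    return WaterCountSeries(
        times_ps=times,
        counts=counts,
        temperatures_K=schedule.temperature_at(times),
        residue_labels=["ref_1"],
        residue_names=["LYS"],
    )
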