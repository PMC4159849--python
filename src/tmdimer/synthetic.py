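"""Synthetic two-helix trajectories with planted interface states.

Self-assembly simulations of a transmembrane-helix dimer visit a small
set of discrete interface architectures, each characterised by how the
two helices are rotated about their own axes, how their axes cross, and
how far apart they sit.  This module plants such states explicitly:

* :class:`InterfaceState` -- one interface geometry (azimuthal rotation
  of each helix, signed crossing angle, inter-axis separation);
* :class:`MarkovInterfaceModel` -- a continuous-time Markov jump process
  over interface states with exponential dwell times, rendered into CG
  coordinate frames with isotropic Gaussian bead noise;
* :class:`ConditionSpec` -- a per-condition (e.g. per-lipid) frequency
  distribution over interface states, used to emulate ensembles of
  independent short self-assembly runs.

The generator targets statistical fidelity (dwell statistics, contact
map separability, condition-dependent frequencies), not physical
realism: there is no force field, membrane or energetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import BeadStructure, Frame, Trajectory, build_ideal_cg_helix


@dataclass(frozen=True)
class InterfaceState:
    """One discrete dimer-interface geometry.

    Attributes
    ----------
    state_id : str
    phi_a, phi_b : float
        Azimuthal rotation (degrees) of helix A / B about its own axis;
        controls which residues face the partner helix.
    crossing_angle : float
        Signed helix-helix crossing angle in degrees; negative values
        are right-handed crossings (the NMR glycophorin A dimer is
        about -40 degrees).
    separation : float
        Inter-axis distance (nm) at closest approach.
    """

    state_id: str
    phi_a: float
    phi_b: float
    crossing_angle: float
    separation: float

    def __post_init__(self):
        if self.separation <= 0:
            raise ValueError("separation must be > 0")
        for name in ("phi_a", "phi_b", "crossing_angle"):
            v = getattr(self, name)
            if not -180.0 < v <= 180.0:
                raise ValueError(f"{name} must lie in (-180, 180], got {v}")


#: Default planted states: two near-parallel interfaces on distinct
#: helix faces plus two right-handed crossed interfaces, one of them an
#: "NMR-like" -40 deg geometry.  Separations (0.60-0.65 nm inter-axis)
#: correspond to close CG helix packing; they keep every planted dimer
#: above the 19-contact stable-dimer threshold, with the crossed states
#: packing tighter than the parallel ones as GxxxG-like interfaces do.
DEFAULT_STATES = (
    InterfaceState("parallel-sym", 0.0, 180.0, 0.0, 0.65),
    InterfaceState("parallel-rot", 120.0, -60.0, 4.0, 0.65),
    InterfaceState("right-handed-asym", -120.0, 60.0, -32.0, 0.60),
    InterfaceState("nmr-like", 60.0, -120.0, -40.0, 0.60),
)


@dataclass
class MarkovInterfaceModel:
    """Continuous-time Markov switching among interface states.

    ``transition_matrix`` is the embedded jump chain (rows sum to one,
    zero diagonal); ``mean_dwell`` holds the exponential mean dwell time
    of each state in ns.  ``noise_sigma`` is the isotropic per-bead
    Gaussian displacement (nm) applied to rendered frames; the default
    0.05 nm makes contact maps fluctuate without destroying the planted
    interfaces.
    """

    states: tuple[InterfaceState, ...] = DEFAULT_STATES
    transition_matrix: np.ndarray | None = None
    mean_dwell: np.ndarray | None = None
    noise_sigma: float = 0.05
    seed: int = 0
    n_residues: int = 25
    first_residue: int = 72

    def __post_init__(self):
        k = len(self.states)
        if self.transition_matrix is None:
            # uniform jumps to the other states
            self.transition_matrix = (np.ones((k, k)) - np.eye(k)) / max(k - 1, 1)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.mean_dwell is None:
            self.mean_dwell = np.full(k, 100.0)
        self.mean_dwell = np.asarray(self.mean_dwell, dtype=float)
        if self.transition_matrix.shape != (k, k):
            raise ValueError("transition matrix shape must match number of states")
        if k > 1 and not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(np.diag(self.transition_matrix) != 0):
            raise ValueError("transition matrix diagonal must be 0")
        if np.any(self.mean_dwell <= 0):
            raise ValueError("mean dwell times must be > 0")

    @property
    def state_ids(self) -> list[str]:
        return [s.state_id for s in self.states]

    def helix_template(self) -> BeadStructure:
        return build_ideal_cg_helix(
            self.n_residues, chain_id="A", first_residue=self.first_residue
        )


@dataclass(frozen=True)
class ConditionSpec:
    """A condition (emulating a lipid species) with its own state frequencies."""

    condition_id: str
    state_frequencies: dict[str, float]

    def __post_init__(self):
        total = sum(self.state_frequencies.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"state frequencies must sum to 1, got {total}")
        if any(p < 0 for p in self.state_frequencies.values()):
            raise ValueError("state frequencies must be non-negative")


# -- geometry --------------------------------------------------------------


def _rot_z(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def place_dimer(
    helix_a: BeadStructure,
    helix_b: BeadStructure,
    state: InterfaceState,
    time: float = 0.0,
    box: np.ndarray | None = None,
) -> Frame:
    """Build one dimer frame realising an interface state.

    Helix A is centred at the origin with its axis along z and rotated
    by ``phi_a`` about z.  Helix B is rotated by ``phi_b`` about its own
    axis, tilted by ``crossing_angle`` about the x axis, and shifted by
    ``separation`` along x.  Both inputs must be helices built along z
    (e.g. from :func:`~tmdimer.structures.build_ideal_cg_helix`) with
    equal residue counts.

    A minimum inter-chain bead distance below 0.1 nm triggers a warning
    (steric overlap), not an error.
    """
    import warnings

    na = len(helix_a.residues(helix_a.chains[0]))
    nb = len(helix_b.residues(helix_b.chains[0]))
    if na != nb:
        raise ValueError("helices must have equal residue counts")

    center_a = helix_a.positions.mean(axis=0)
    center_b = helix_b.positions.mean(axis=0)
    pos_a = (helix_a.positions - center_a) @ _rot_z(state.phi_a).T
    pos_b = (helix_b.positions - center_b) @ _rot_z(state.phi_b).T
    pos_b = pos_b @ _rot_x(state.crossing_angle).T + np.array([state.separation, 0.0, 0.0])

    a = helix_a.relabelled("A").with_positions(pos_a)
    b = helix_b.relabelled("B").with_positions(pos_b)
    structure = BeadStructure.merge(a, b)

    diff = pos_a[:, None, :] - pos_b[None, :, :]
    min_dist = np.sqrt((diff**2).sum(axis=-1)).min()
    if min_dist < 0.1:
        warnings.warn(
            f"placed dimer has bead overlap (min distance {min_dist:.3f} nm)",
            stacklevel=2,
        )
    return Frame(structure, time=time, box=box)


# -- Markov sampling -------------------------------------------------------


def sample_state_sequence(
    model: MarkovInterfaceModel, duration: float, seed: int | None = None
):
    """Sample the jump process over ``[0, duration)``.

    Returns
    -------
    entry_times : ndarray
        Time each visited state was entered (starts at 0).
    state_indices : ndarray of int
        Index into ``model.states`` for each visit.
    dwells : ndarray
        Exact dwell duration of each visit; the last one is truncated
        at ``duration``.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    k = len(model.states)
    state = int(rng.integers(k))
    t = 0.0
    entry_times, state_indices, dwells = [], [], []
    while t < duration:
        dwell = rng.exponential(model.mean_dwell[state])
        entry_times.append(t)
        state_indices.append(state)
        dwells.append(min(dwell, duration - t))
        t += dwell
        if t < duration and k > 1:
            state = int(rng.choice(k, p=model.transition_matrix[state]))
    return np.array(entry_times), np.array(state_indices, dtype=int), np.array(dwells)


def labels_at_times(
    entry_times: np.ndarray, state_indices: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """State index active at each query time (jumps resolved at frame resolution)."""
    idx = np.searchsorted(entry_times, times, side="right") - 1
    return state_indices[np.clip(idx, 0, len(state_indices) - 1)]


def simulate_interface_markov(
    model: MarkovInterfaceModel,
    duration: float,
    dt: float,
    seed: int | None = None,
    helix_template: BeadStructure | None = None,
):
    """Render a Markov-switching dimer trajectory.

    Frames are stored at times ``0, dt, 2*dt, ...`` strictly below
    ``duration``; each frame is the current state's ideal dimer plus
    isotropic Gaussian bead noise of sd ``model.noise_sigma``.  The same
    seed yields a bit-identical trajectory.

    Returns
    -------
    trajectory : Trajectory
    labels : ndarray of str
        True generating state id per stored frame.
    """
    if duration < dt:
        raise ValueError("duration must be >= dt")
    base_seed = model.seed if seed is None else seed
    entry_times, state_indices, _ = sample_state_sequence(model, duration, seed=base_seed)
    times = np.arange(0.0, duration, dt)
    frame_states = labels_at_times(entry_times, state_indices, times)

    helix = helix_template if helix_template is not None else model.helix_template()
    noise_rng = np.random.default_rng((base_seed, 0x5EED))
    frames = []
    for t, si in zip(times, frame_states):
        frame = place_dimer(helix, helix, model.states[si], time=float(t))
        if model.noise_sigma > 0:
            noisy = frame.structure.positions + noise_rng.normal(
                0.0, model.noise_sigma, size=frame.structure.positions.shape
            )
            frame = Frame(frame.structure.with_positions(noisy), time=float(t))
        frames.append(frame)
    labels = np.array([model.states[si].state_id for si in frame_states], dtype=object)
    return Trajectory(frames, dt), labels


def sample_condition_assemblies(
    condition: ConditionSpec, n_simulations: int, seed: int = 0
) -> list[str]:
    """Draw i.i.d. final-assembly state labels for one condition.

    Emulates an ensemble of independent short self-assembly runs whose
    final interfaces follow the condition's state-frequency vector.
    """
    if n_simulations < 1:
        raise ValueError("n_simulations must be >= 1")
    rng = np.random.default_rng(seed)
    ids = list(condition.state_frequencies.keys())
    probs = np.array([condition.state_frequencies[i] for i in ids])
    return [ids[i] for i in rng.choice(len(ids), size=n_simulations, p=probs)]


def render_assembly_frames(
    model: MarkovInterfaceModel,
    labels: list[str],
    seed: int = 0,
    dt: float = 1.0,
) -> list[Frame]:
    """Render one noisy frame per final-assembly label (not a time series)."""
    rng = np.random.default_rng(seed)
    helix = model.helix_template()
    by_id = {s.state_id: s for s in model.states}
    frames = []
    for k, label in enumerate(labels):
        frame = place_dimer(helix, helix, by_id[label], time=float(k) * dt)
        if model.noise_sigma > 0:
            noisy = frame.structure.positions + rng.normal(
                0.0, model.noise_sigma, size=frame.structure.positions.shape
            )
            frame = Frame(frame.structure.with_positions(noisy), time=float(k) * dt)
        frames.append(frame)
    return frames
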