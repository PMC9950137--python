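"""Synthetic-data generators with recorded ground truth.

Every input the analysis stages consume can be generated here: amino-acid
alignments evolved along a tree under an empirical model with discrete-gamma
rates and clade-restricted block indels; stopped-flow photodiode-array
matrices from the closed-form two-step sequential model; Michaelis-Menten
initial-rate designs; single-exponential traces; melt curves; and
conversion-area tables.  Each generator takes a seed and returns, alongside
the data, a truth record sufficient to score the corresponding analysis
stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evomodel import AMINO_ACIDS, N_STATES, SubstitutionModel
from .formats import GAP, Alignment, PhyloTree
from .kinetics import InitialRateDataset, StoppedFlowMatrix, sequential_concentrations


@dataclass
class IndelBlock:
    """A contiguous block deletion on the branch above a named node; the
    absence is inherited by the whole clade below."""

    node: str
    start: int  # 1-based alignment column, inclusive
    end: int  # inclusive

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad indel block [{self.start}, {self.end}]")


@dataclass
class SimulationTruth:
    """Ground truth for one synthetic dataset."""

    seed: int | None
    params: dict = field(default_factory=dict)
    ancestral_sequences: dict[str, str] = field(default_factory=dict)
    presence: dict[str, np.ndarray] = field(default_factory=dict)
    site_rates: np.ndarray | None = None


def _label_internals(tree: PhyloTree) -> None:
    i = 0
    for node in tree.postorder():
        if not node.is_leaf and node.label is None:
            i += 1
            node.label = f"N{i}"


def simulate_alignment(
    tree: PhyloTree,
    model: SubstitutionModel,
    n_sites: int,
    indel_spec: list[IndelBlock] | None = None,
    seed: int | None = None,
) -> tuple[Alignment, SimulationTruth]:
    """Evolve an alignment along a rooted tree.

    The root sequence is drawn from the model's equilibrium frequencies; one
    gamma rate category is drawn per site and shared across the whole tree
    (the among-site rate model the likelihood assumes); each branch then
    substitutes sites independently via P(Q t r).  ``indel_spec`` deletes
    contiguous column blocks on the branch above named nodes, with absence
    inherited by every descendant — emulating clade-restricted gaps.  Truth
    records the sequence and presence mask at every internal node.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    for blk in indel_spec or []:
        if blk.end > n_sites:
            raise ValueError(
                f"indel block [{blk.start}, {blk.end}] outside 1..{n_sites}"
            )
    tree = tree.copy()
    _label_internals(tree)
    rng = np.random.default_rng(seed)
    cats = rng.integers(0, model.K, size=n_sites)
    site_rates = model.rates[cats]
    aa = np.array(list(AMINO_ACIDS))

    states: dict = {}
    present: dict = {}
    root = tree.root
    states[root] = rng.choice(N_STATES, size=n_sites, p=model.pi)
    present[root] = np.ones(n_sites, dtype=bool)
    deletions = {}
    for blk in indel_spec or []:
        deletions.setdefault(blk.node, []).append(blk)

    for node in tree.preorder():
        if node is root:
            continue
        parent = node.parent
        child_states = states[parent].copy()
        # per-category transition sampling; zero-length branches copy states
        if node.length > 0:
            for k in np.unique(cats):
                P = model.transition_matrix(node.length, model.rates[k])
                sel = np.flatnonzero(cats == k)
                cum = np.cumsum(P[states[parent][sel]], axis=1)
                u = rng.random(len(sel))
                child_states[sel] = (u[:, None] < cum).argmax(axis=1)
        mask = present[parent].copy()
        for blk in deletions.get(node.label, []):
            mask[blk.start - 1 : blk.end] = False
        states[node] = child_states
        present[node] = mask

    def seq_of(node) -> str:
        chars = aa[states[node]]
        chars = np.where(present[node], chars, GAP)
        return "".join(chars)

    leaves = tree.leaves()
    alignment = Alignment([n.label for n in leaves], [seq_of(n) for n in leaves])
    truth = SimulationTruth(
        seed=seed,
        params={
            "n_sites": n_sites,
            "model": model.name,
            "alpha": model.alpha,
            "K": model.K,
            "tree": tree.to_newick(),
        },
        ancestral_sequences={
            n.label: seq_of(n) for n in tree.postorder() if not n.is_leaf
        },
        presence={n.label: present[n] for n in tree.postorder() if not n.is_leaf},
        site_rates=site_rates,
    )
    return alignment, truth


def default_species_spectra(
    wavelengths: np.ndarray,
    peaks: tuple = ((370.0, 30.0, 0.35), (380.0, 25.0, 0.55), (450.0, 28.0, 0.8)),
) -> np.ndarray:
    """Gaussian-peak species spectra for the three states of the oxidative
    half-reaction: reduced flavin (a), the C4a-(hydro)peroxyflavin-like
    intermediate peaking near 380 nm (b), and oxidised flavin (c)."""
    wl = np.asarray(wavelengths, float)
    out = np.empty((3, len(wl)))
    for i, (center, width, amp) in enumerate(peaks):
        out[i] = amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return out


def simulate_stopped_flow(
    k1: float,
    k2: float,
    t_grid: np.ndarray,
    wl_grid: np.ndarray,
    spectra: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[StoppedFlowMatrix, SimulationTruth]:
    """Photodiode-array matrix from the two-step model a -> b -> c plus
    i.i.d. Gaussian noise."""
    if k1 <= 0 or k2 <= 0:
        raise ValueError("rate constants must be positive")
    if noise_sd < 0:
        raise ValueError("negative noise_sd")
    t = np.asarray(t_grid, float)
    wl = np.asarray(wl_grid, float)
    if t.size == 0 or wl.size == 0:
        raise ValueError("empty time or wavelength grid")
    S = default_species_spectra(wl) if spectra is None else np.asarray(spectra, float)
    C = sequential_concentrations(k1, k2, t)
    A = C @ S
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        A = A + rng.normal(0.0, noise_sd, size=A.shape)
    truth = SimulationTruth(
        seed=seed,
        params={"k1": k1, "k2": k2, "noise_sd": noise_sd, "spectra": S},
    )
    return StoppedFlowMatrix(times=t, wavelengths=wl, absorbance=A, truth=truth.params), truth


def simulate_initial_rates(
    km: float,
    vmax: float,
    conc_grid: np.ndarray,
    n_rep: int = 3,
    noise_frac: float = 0.05,
    seed: int | None = None,
    conc_unit: str = "uM",
    rate_unit: str = "s-1",
    enzyme_conc_uM: float | None = None,
) -> tuple[InitialRateDataset, SimulationTruth]:
    """Initial-rate design v = Vmax S / (K_M + S) with multiplicative
    Gaussian noise of relative standard deviation ``noise_frac``."""
    if km <= 0 or vmax <= 0:
        raise ValueError("K_M and Vmax must be positive")
    conc = np.repeat(np.asarray(conc_grid, float), n_rep)
    replicate = np.tile(np.arange(n_rep), len(conc_grid))
    rng = np.random.default_rng(seed)
    v = vmax * conc / (km + conc)
    if noise_frac > 0:
        v = v * (1.0 + rng.normal(0.0, noise_frac, size=v.shape))
    truth = SimulationTruth(
        seed=seed,
        params={"km": km, "vmax": vmax, "noise_frac": noise_frac,
                "conc_unit": conc_unit},
    )
    ds = InitialRateDataset(
        conc=conc, rate=v, conc_unit=conc_unit, rate_unit=rate_unit,
        enzyme_conc_uM=enzyme_conc_uM, replicate=replicate, truth=truth.params,
    )
    return ds, truth


def simulate_trace_exponential(
    k: float,
    a0: float,
    a_inf: float,
    t_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, SimulationTruth]:
    """Single-exponential trace A(t) = A_inf + (A0 - A_inf) e^{-kt} + noise."""
    if k <= 0:
        raise ValueError("k must be positive")
    t = np.asarray(t_grid, float)
    A = a_inf + (a0 - a_inf) * np.exp(-k * t)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        A = A + rng.normal(0.0, noise_sd, size=A.shape)
    truth = SimulationTruth(
        seed=seed, params={"k": k, "a0": a0, "a_inf": a_inf, "noise_sd": noise_sd}
    )
    return t, A, truth


def simulate_melt_curve(
    tm: float,
    slope: float = 1.5,
    t_min: float = 25.0,
    t_max: float = 95.0,
    n_points: int = 141,
    baseline: float = 100.0,
    amplitude: float = 900.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, SimulationTruth]:
    """Logistic unfolding curve F(T) = baseline + amplitude / (1 + e^{-(T-Tm)/s})."""
    T = np.linspace(t_min, t_max, n_points)
    F = baseline + amplitude / (1.0 + np.exp(-(T - tm) / slope))
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        F = F + rng.normal(0.0, noise_sd, size=F.shape)
    truth = SimulationTruth(seed=seed, params={"tm": tm, "slope": slope})
    return T, F, truth


def simulate_conversion_table(
    depletions: dict[str, float],
    control_substrate_area: float = 1e6,
    is_area: float = 2e5,
    noise_frac: float = 0.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Peak-area table for conversion assays.

    ``depletions`` maps sample name -> fraction of substrate consumed
    (0..1).  A no-enzyme control row named 'control' is always included.
    """
    rng = np.random.default_rng(seed)
    rows = [{"sample": "control",
             "substrate_area": control_substrate_area,
             "is_area": is_area}]
    for name, frac in depletions.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"depletion for {name!r} outside [0, 1]")
        area = control_substrate_area * (1.0 - frac)
        isa = is_area
        if noise_frac > 0:
            area *= 1.0 + rng.normal(0.0, noise_frac)
            isa *= 1.0 + rng.normal(0.0, noise_frac)
        rows.append({"sample": name, "substrate_area": area, "is_area": isa})
    truth = SimulationTruth(seed=seed, params={"depletions": dict(depletions)})
    return pd.DataFrame(rows), truth
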