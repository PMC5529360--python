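"""Synthetic trajectories and patient cohorts with known ground truth.

The study's inputs — 10 ns production runs sampled every 2 ps (5000 frames)
of EGFR kinase-domain/inhibitor complexes, and a 68-patient registry — are
not publicly deposited.  These generators emulate their *statistical*
structure so that every stochastic test can be scored against a known
ground truth:

* trajectories: a fixed heavy-atom reference with residues laid out along a
  coarse 3D curve (so distance-to-focal-residue ordering is nontrivial),
  per-frame isotropic Gaussian fluctuation with a chosen per-residue sigma,
  optional per-frame rigid-body jitter (uniform random axis/angle rotation
  plus a uniform translation) and an optional AR(1) mode for temporally
  correlated noise;
* cohorts: categorical attributes drawn from marginal probabilities (age
  thresholds derived from a single latent age so their monotonicity holds
  by construction), with a binary outcome from a logistic model whose
  per-attribute odds multipliers are the recoverable effects.

No force field, thermostat or solvent: the generator reproduces the
fluctuation statistics the analysis consumes, not the physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .model import AtomRecord, StructureFrame, Topology, Trajectory

KINASE_DOMAIN_START = 697
KINASE_DOMAIN_END = 1019

_AA3 = ("ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL")


# ---------------------------------------------------------------------------
# trajectories

@dataclass(frozen=True)
class RigidJitter:
    """Per-frame rigid-body drift: rotation axis uniform on the sphere,
    angle uniform in [0, max_rotation_deg], translation uniform in the cube
    [-max_translation_A, +max_translation_A]^3."""

    max_rotation_deg: float = 5.0
    max_translation_A: float = 1.0


@dataclass(frozen=True)
class TrajectoryRecipe:
    """Recipe for one synthetic kinase-domain-like trajectory.

    Defaults mirror the emulated study conditions: residue numbering starts
    at 697, atoms_per_residue=8 heavy atoms, J=5000 frames at 2 ps.  The
    default fluctuation scale of 0.3 A per coordinate is a typical
    ordered-domain amplitude; ``per_residue_sigma`` may be a scalar or one
    value per residue.  ``ar1_phi`` > 0 switches to stationary AR(1) noise
    with the same marginal sigma (the stability statistic is frame-order
    agnostic, so this exists to demonstrate that invariance).
    """

    n_residues: int = 323
    atoms_per_residue: Union[int, Sequence[int]] = 8
    residue_number_start: int = KINASE_DOMAIN_START
    deletion_gaps: Tuple[Tuple[int, int], ...] = ()
    per_residue_sigma: Union[float, Sequence[float]] = 0.3
    rigid_jitter: Optional[RigidJitter] = None
    ar1_phi: float = 0.0
    n_frames: int = 5000
    frame_interval_ps: float = 2.0
    seed: int = 0

    def residue_numbers(self) -> np.ndarray:
        nums = []
        n = self.residue_number_start
        while len(nums) < self.n_residues:
            if not any(lo <= n <= hi for lo, hi in self.deletion_gaps):
                nums.append(n)
            n += 1
        return np.asarray(nums, dtype=np.int64)

    def atoms_per_residue_array(self) -> np.ndarray:
        if np.isscalar(self.atoms_per_residue):
            return np.full(self.n_residues, int(self.atoms_per_residue))
        arr = np.asarray(self.atoms_per_residue, dtype=np.int64)
        if len(arr) != self.n_residues:
            raise ValueError("atoms_per_residue list must match n_residues")
        return arr

    def sigma_array(self) -> np.ndarray:
        if np.isscalar(self.per_residue_sigma):
            sig = np.full(self.n_residues, float(self.per_residue_sigma))
        else:
            sig = np.asarray(self.per_residue_sigma, dtype=np.float64)
            if len(sig) != self.n_residues:
                raise ValueError("per_residue_sigma list must match n_residues")
        if np.any(sig < 0):
            raise ValueError("sigmas must be non-negative")
        return sig


def make_reference(recipe: TrajectoryRecipe) -> StructureFrame:
    """Deterministic pseudo-random heavy-atom reference structure.

    Residue centroids follow a gently turning helix-like space curve with
    ~3.8 A spacing, so centroid distances to any focal residue vary
    smoothly but non-monotonically with sequence separation; atoms sit at
    seeded offsets (<= ~1.5 A) around their centroid.
    """
    rng = np.random.default_rng([int(recipe.seed) % (2**31), 101])
    nums = recipe.residue_numbers()
    kper = recipe.atoms_per_residue_array()
    t = np.arange(recipe.n_residues, dtype=np.float64)
    # coarse curve: superhelix with slow secondary wobble
    centroids = np.stack([
        10.0 * np.cos(0.35 * t) + 3.0 * np.sin(0.05 * t),
        10.0 * np.sin(0.35 * t) + 3.0 * np.cos(0.07 * t),
        1.6 * t,
    ], axis=1)
    atoms: List[AtomRecord] = []
    coords: List[np.ndarray] = []
    aid = 0
    for r in range(recipe.n_residues):
        resname = _AA3[int(rng.integers(len(_AA3)))]
        offsets = rng.uniform(-1.5, 1.5, size=(kper[r], 3))
        for k in range(kper[r]):
            atoms.append(AtomRecord(atom_id=aid, name=f"X{k}", element="C",
                                    residue_number=int(nums[r]),
                                    residue_name=resname))
            coords.append(centroids[r] + offsets[k])
            aid += 1
    return StructureFrame(Topology(atoms), np.asarray(coords))


def _random_rotation(rng, max_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def generate_trajectory(reference: StructureFrame,
                        recipe: TrajectoryRecipe) -> Trajectory:
    """Reference + per-residue Gaussian fluctuation (+ optional rigid drift).

    Frame j is ``jitter_j(reference + noise_j)`` with independent isotropic
    Gaussian noise of the residue's sigma per coordinate (AR(1)-correlated
    across frames when ``ar1_phi`` > 0, same marginal sigma).  The true
    sigma profile is recorded in ``Trajectory.provenance``.
    """
    rng = np.random.default_rng([int(recipe.seed) % (2**31), 202])
    top = reference.topology
    if top.n_residues != recipe.n_residues:
        raise ValueError("reference does not match recipe (n_residues)")
    sig = recipe.sigma_array()
    sigma_per_atom = np.repeat(sig, top.residue_sizes)[None, :, None]
    J = recipe.n_frames
    coords = np.empty((J, top.n_atoms, 3))
    phi = float(recipe.ar1_phi)
    if not 0.0 <= phi < 1.0:
        raise ValueError("ar1_phi must be in [0, 1)")
    noise = rng.normal(size=(top.n_atoms, 3)) * sigma_per_atom[0]
    innov_scale = np.sqrt(1.0 - phi * phi)
    for j in range(J):
        if j > 0:
            eps = rng.normal(size=(top.n_atoms, 3)) * sigma_per_atom[0]
            noise = phi * noise + innov_scale * eps if phi > 0 else eps
        frame = reference.coordinates + noise
        if recipe.rigid_jitter is not None:
            R = _random_rotation(rng, recipe.rigid_jitter.max_rotation_deg)
            tvec = rng.uniform(-recipe.rigid_jitter.max_translation_A,
                               recipe.rigid_jitter.max_translation_A, size=3)
            center = frame.mean(axis=0)
            frame = (frame - center) @ R.T + center + tvec
        coords[j] = frame
    prov = {"generator": "resiflex.synthetic.generate_trajectory",
            "recipe": asdict(recipe),
            "true_sigma": sig.tolist(),
            "seed": int(recipe.seed)}
    return Trajectory(top, coords, recipe.frame_interval_ps, provenance=prov)


def hot_loop_sigma(recipe_n_residues: int, focal_index: int,
                   hot_width: int, hot_sigma: float,
                   cold_sigma: float) -> np.ndarray:
    """Sigma profile: ``hot_sigma`` within ``hot_width`` residues (in index
    space) of ``focal_index``, ``cold_sigma`` elsewhere."""
    sig = np.full(recipe_n_residues, float(cold_sigma))
    lo = max(0, focal_index - hot_width)
    hi = min(recipe_n_residues, focal_index + hot_width + 1)
    sig[lo:hi] = float(hot_sigma)
    return sig


# ---------------------------------------------------------------------------
# cohorts

#: default marginal probabilities, mirroring the study cohort's margins
DEFAULT_COHORT_MARGINALS: Dict[str, object] = {
    "sex": {"male": 14 / 68, "female": 54 / 68},
    "smoking": {"never": 58 / 68, "chronic": 2 / 68, "ex": 8 / 68},
    "lung_met": 59 / 68,
    "pleural_met": 30 / 68,
    "brain_met": 15 / 68,
    "liver_met": 11 / 68,
    "bone_met": 34 / 68,
    "distant_ln_met": 18 / 68,
    "initial_egfr_mutation": {
        "exon19_LRE_delE746_A750": 31 / 68,
        "exon19_LRE_other": 3 / 68,
        "exon19_nonLRE": 3 / 68,
        "L858R": 31 / 68,
    },
    "number_lines_tki": {1: 53 / 68, 2: 12 / 68, 3: 3 / 68},
    "number_lines_chemo": {0: 44 / 68, 1: 16 / 68, 2: 6 / 68, 3: 2 / 68},
    "first_tki": {"gefitinib": 54 / 68, "erlotinib": 7 / 68,
                  "afatinib": 7 / 68},
}

AGE_THRESHOLDS = (55, 60, 65, 70, 75, 80)


@dataclass(frozen=True)
class CohortRecipe:
    """Recipe for a synthetic patient cohort.

    ``effects`` maps attribute name -> odds multiplier on the outcome when
    the attribute is "active" (a true boolean, or for categoricals a
    ``(attribute, level)`` key given as ``"attribute=level"``).  The outcome
    is drawn from a logistic model: baseline odds correspond to
    ``baseline_outcome_p``, multiplied by each active attribute's factor.
    Defaults match the emulated registry: n=68, ~40% baseline outcome rate.
    """

    n_patients: int = 68
    marginals: Mapping[str, object] = field(
        default_factory=lambda: dict(DEFAULT_COHORT_MARGINALS))
    effects: Mapping[str, float] = field(default_factory=dict)
    baseline_outcome_p: float = 0.4
    age_mean: float = 66.0
    age_sd: float = 9.0
    age_range: Tuple[float, float] = (47.0, 87.0)
    seed: int = 0


def _draw_categorical(rng, levels_probs: Mapping, n: int) -> np.ndarray:
    levels = list(levels_probs.keys())
    p = np.asarray([levels_probs[l] for l in levels], dtype=np.float64)
    p = p / p.sum()
    idx = rng.choice(len(levels), size=n, p=p)
    return np.asarray(levels, dtype=object)[idx]


def generate_cohort(recipe: CohortRecipe) -> pd.DataFrame:
    """Draw a cohort table with known attribute-outcome effects.

    Age-threshold booleans come from one latent age draw (monotone by
    construction); the number of metastatic sites is the count of true
    site flags, floored at 1; TKI/chemo usage flags are derived from the
    drawn line counts.  Returns a DataFrame in the standard cohort schema
    with a boolean ``t790m`` outcome.
    """
    rng = np.random.default_rng([int(recipe.seed) % (2**31), 303])
    n = int(recipe.n_patients)
    m = dict(recipe.marginals)
    cols: Dict[str, np.ndarray] = {}

    age = np.clip(rng.normal(recipe.age_mean, recipe.age_sd, size=n),
                  *recipe.age_range)
    for thr in AGE_THRESHOLDS:
        cols[f"age_{thr}"] = age >= thr

    cols["sex"] = _draw_categorical(rng, m["sex"], n)
    cols["smoking"] = _draw_categorical(rng, m["smoking"], n)
    site_names = ["lung_met", "pleural_met", "brain_met", "liver_met",
                  "bone_met", "distant_ln_met"]
    for s in site_names:
        cols[s] = rng.random(n) < float(m[s])
    n_sites = np.sum([cols[s] for s in site_names], axis=0)
    cols["number_sites_met"] = np.maximum(n_sites, 1).astype(np.int64)
    cols["initial_egfr_mutation"] = _draw_categorical(
        rng, m["initial_egfr_mutation"], n)
    lines_tki = _draw_categorical(rng, m["number_lines_tki"], n).astype(np.int64)
    lines_chemo = _draw_categorical(rng, m["number_lines_chemo"], n).astype(np.int64)
    cols["number_lines_tki"] = lines_tki
    cols["number_lines_chemo"] = lines_chemo
    cols["first_tki"] = _draw_categorical(rng, m["first_tki"], n)
    cols["second_tki_used"] = lines_tki >= 2
    cols["third_tki_used"] = lines_tki >= 3
    cols["first_chemo_used"] = lines_chemo >= 1
    cols["second_chemo_used"] = lines_chemo >= 2
    cols["third_chemo_used"] = lines_chemo >= 3

    base_odds = recipe.baseline_outcome_p / (1.0 - recipe.baseline_outcome_p)
    log_odds = np.full(n, np.log(base_odds))
    for key, mult in recipe.effects.items():
        if mult <= 0:
            raise ValueError(f"odds multiplier for {key} must be positive")
        if "=" in key:
            attr, level = key.split("=", 1)
            active = cols[attr].astype(str) == level
        else:
            active = cols[key].astype(bool)
        log_odds = log_odds + np.where(active, np.log(mult), 0.0)
    p = 1.0 / (1.0 + np.exp(-log_odds))
    cols["t790m"] = rng.random(n) < p

    if n == 0:
        return pd.DataFrame({k: pd.Series(dtype=object) for k in cols})
    df = pd.DataFrame(cols)
    df.attrs["provenance"] = {
        "generator": "resiflex.synthetic.generate_cohort",
        "seed": int(recipe.seed),
        "effects": dict(recipe.effects),
        "baseline_outcome_p": recipe.baseline_outcome_p,
    }
    return df
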