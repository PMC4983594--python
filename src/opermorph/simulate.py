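"""Synthetic outline-shape datasets with known ground truth.

Generates everything the analysis pipeline consumes — a TPS landmark file,
a specimen classifier CSV, a Newick species tree, and a ground-truth JSON —
with the statistical structure the morphometric analysis assumes:

* species mean outlines evolve by Brownian motion on a Yule tree, in the
  space of radial-Fourier coefficients of a smooth opercle-like blob;
* freshwater (and half-strength brackish) species get an
  anterior-posterior stretch with dorsal-ventral compression,
  x -> x (1 + delta), y -> y / (1 + delta), applied to the dense outline
  before landmark resampling;
* each specimen draws a lognormal centroid size and a size-linked
  (allometric) shape component;
* left and right sides differ by a directional asymmetry offset plus side
  noise; the right side is mirrored as a digitized right opercle would be;
* isotropic digitization noise is added to the final landmarks.

Identical config + seed produce byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np

from .landmark_io import (
    LandmarkConfiguration,
    OutlinePolyline,
    reflect,
    resample_equidistant,
    write_tps,
)
from .phylo import PhyloTree, read_newick

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_tree",
    "simulate_bm_traits",
    "base_outline_coefficients",
    "generate_dataset",
]

N_HARMONICS = 8
DENSE_POINTS = 2000


def base_outline_coefficients() -> np.ndarray:
    """Radial-Fourier amplitudes of a smooth opercle-like blob.

    Layout: [a_1..a_H, b_1..b_H] in r(theta) = r0 (1 + sum a_h cos(h theta)
    + b_h sin(h theta)). The defaults give a gently triangular outline with
    a flatter ventral edge, loosely resembling a teleost opercle in lateral
    view.
    """
    a = np.zeros(N_HARMONICS)
    b = np.zeros(N_HARMONICS)
    a[0], b[0] = 0.12, -0.06  # elongation / tilt
    a[1], b[1] = -0.08, 0.04  # triangularity
    a[2], b[2] = 0.05, -0.02
    a[3] = 0.02
    return np.concatenate([a, b])


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic-data generator.

    Defaults emulate a museum-scale sampling design: ~20 species on an
    ultrametric tree, multiple specimens per species with two sides each
    (a few with one), Brownian among-species shape variation, a habitat
    stretch for freshwater/brackish species, allometry, side asymmetry,
    and digitization noise.
    """

    n_species: int = 20
    birth_rate: float = 1.0
    tree_newick: str | None = None
    n_specimens_per_species: int = 13
    k_landmarks: int = 100
    base_coefficients: np.ndarray = field(default_factory=base_outline_coefficients)
    bm_rate: float = 0.004
    habitat_assignment: dict | None = None
    habitat_effect: float = 0.08
    allometry_slope: float = 0.02
    allometry_on_log_size: bool = True
    size_meanlog: float = 3.0
    size_sdlog: float = 0.25
    side_asymmetry_offset: float = 0.003
    side_asymmetry_sd: float = 0.002
    specimen_coeff_sd: float = 0.01
    digitization_noise_sd: float = 0.001
    missing_side_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.habitat_effect <= -1:
            raise ValueError("habitat_effect must be > -1")
        for name in ("bm_rate", "side_asymmetry_sd", "specimen_coeff_sd",
                     "digitization_noise_sd", "size_sdlog"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.missing_side_fraction <= 1):
            raise ValueError("missing_side_fraction must be in [0, 1]")
        if self.habitat_assignment is not None:
            bad = set(self.habitat_assignment.values()) - {"f", "b", "m"}
            if bad:
                raise ValueError(f"invalid habitat codes: {sorted(bad)}")


@dataclass
class SimulatedDataset:
    """In-memory synthetic dataset plus ground truth."""

    configs: list          # (LandmarkConfiguration, metadata) pairs, TPS order
    classifier: "object"   # pandas DataFrame
    tree: PhyloTree
    newick: str
    truth: dict

    def write(self, out_dir) -> dict:
        """Write tps/csv/newick/json files; returns the path map."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "tps": out / "landmarks.tps",
            "classifier": out / "classifier.csv",
            "newick": out / "tree.nwk",
            "truth": out / "truth.json",
        }
        write_tps(self.configs, paths["tps"])
        self.classifier.to_csv(paths["classifier"], index=False)
        paths["newick"].write_text(self.newick)
        paths["truth"].write_text(json.dumps(self.truth, indent=1, sort_keys=True))
        return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# Tree and trait simulation
# ---------------------------------------------------------------------------

def simulate_tree(n_species: int, birth_rate: float = 1.0, seed: int = 0) -> PhyloTree:
    """Yule (pure-birth) tree scaled to unit root-to-tip depth."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    import random

    rng = random.Random(seed)
    dtree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rng,
    )
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:02d}"
    tree = PhyloTree.from_dendropy(dtree)
    # the process stops at the last speciation event, leaving zero-length
    # tip branches; extend all tips by one more exponential waiting time
    extra = rng.expovariate(n_species * birth_rate)
    tip_edge = tree.edges[:, 1] < tree.n_tips
    tree.edge_lengths[tip_edge] += extra
    depth = tree.tip_depths().max()
    tree.edge_lengths = tree.edge_lengths / depth
    return tree


def simulate_bm_traits(
    tree: PhyloTree, dimension: int, rate: float, seed: int = 0
) -> np.ndarray:
    """Brownian motion on the tree: root 0, branch increments N(0, rate*t).

    Returns (n_tips, dimension) tip values.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    values = np.zeros((tree.n_nodes, dimension))
    # edges are preorder: parent values set before children
    for (p, c), length in zip(tree.edges, tree.edge_lengths):
        values[c] = values[p] + rng.normal(
            0.0, np.sqrt(rate * max(length, 0.0)), size=dimension
        )
    return values[: tree.n_tips]


# ---------------------------------------------------------------------------
# Outline construction
# ---------------------------------------------------------------------------

# a fixed, sharp notch on the ventral anterior edge: the anatomical anchor
# whose curvature maximum defines the Type-2 landmark. It does not evolve,
# so the fixed landmark stays identifiable across species and sizes.
NOTCH_ANGLE = 1.25 * np.pi  # lower-left
NOTCH_DEPTH = 0.12
NOTCH_SHARPNESS = 40.0


def _radial_outline(coeffs: np.ndarray, n_points: int = DENSE_POINTS,
                    r0: float = 1.0) -> np.ndarray:
    """Dense closed polyline of the radial-Fourier curve r(theta)."""
    H = coeffs.size // 2
    a, b = coeffs[:H], coeffs[H:]
    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    h = np.arange(1, H + 1)
    r = r0 * (
        1.0
        + np.cos(np.outer(theta, h)) @ a
        + np.sin(np.outer(theta, h)) @ b
    )
    r = r * (1.0 - NOTCH_DEPTH * np.exp(
        (np.cos(theta - NOTCH_ANGLE) - 1.0) * NOTCH_SHARPNESS
    ))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _clamp_coefficients(coeffs: np.ndarray, rng: np.random.Generator,
                        redraw_sd: float, max_tries: int = 50) -> np.ndarray:
    """Ensure the radius stays positive; reject-and-redraw the deviation."""
    base = base_outline_coefficients()
    out = coeffs
    for _ in range(max_tries):
        theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        H = out.size // 2
        h = np.arange(1, H + 1)
        r = 1.0 + np.cos(np.outer(theta, h)) @ out[:H] + np.sin(np.outer(theta, h)) @ out[H:]
        if r.min() > 0.15:
            return out
        out = base + rng.normal(0.0, redraw_sd, size=base.size)
    raise RuntimeError("could not draw a simple closed outline")


def _fixed_landmark_start(dense: np.ndarray) -> np.ndarray:
    """Dense-curve point of maximum concave curvature on the lower-left arc.

    The analog of the single fixed (Type 2) landmark: the curvature
    extremum of the notch on the ventral part of the anterior edge. Signed
    curvature is used so the notch center (the unique concavity of an
    otherwise convex outline) wins over its convex shoulders.
    """
    centroid = dense.mean(axis=0)
    rel = dense - centroid
    # discrete signed curvature via second differences (closed CCW curve)
    d1 = (np.roll(dense, -1, axis=0) - np.roll(dense, 1, axis=0)) / 2.0
    d2 = np.roll(dense, -1, axis=0) - 2 * dense + np.roll(dense, 1, axis=0)
    num = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    den = (d1[:, 0] ** 2 + d1[:, 1] ** 2) ** 1.5
    signed = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    lower_left = (rel[:, 0] < 0) & (rel[:, 1] < 0)
    if not lower_left.any():
        lower_left = np.ones(len(dense), dtype=bool)
    idx = np.flatnonzero(lower_left)
    if signed[idx].min() < 0:  # the notch: strongest concavity
        curvature = -signed
    else:  # no concave point: fall back to strongest convexity
        curvature = np.abs(signed)
    j = idx[np.argmax(curvature[idx])]
    # sub-gridpoint refinement: parabolic fit through the curvature peak,
    # then linear interpolation along the polyline (avoids quantization
    # noise in the landmark parameterization)
    n = len(dense)
    cm, c0, cp = curvature[(j - 1) % n], curvature[j], curvature[(j + 1) % n]
    denom = cm - 2 * c0 + cp
    offset = 0.0 if denom >= 0 else float(np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5))
    if offset >= 0:
        return dense[j] + offset * (dense[(j + 1) % n] - dense[j])
    return dense[j] + offset * (dense[j] - dense[(j - 1) % n])


def _habitat_stretch(points: np.ndarray, delta: float) -> np.ndarray:
    """Anterior-posterior stretch with dorsal-ventral compression."""
    out = points.copy()
    out[:, 0] *= 1.0 + delta
    out[:, 1] /= 1.0 + delta
    return out


def _default_habitats(tip_names, rng: np.random.Generator) -> dict:
    """Assign f/b/m roughly 1:2:2, shuffled deterministically."""
    n = len(tip_names)
    codes = (["f"] * max(1, n // 4) + ["b"] * max(1, (2 * n) // 5))
    codes += ["m"] * (n - len(codes))
    codes = list(codes[:n])
    rng.shuffle(codes)
    # make sure all three habitats occur
    for needed, slot in zip("fbm", range(3)):
        if needed not in codes:
            codes[slot] = needed
    return dict(zip(tip_names, codes))


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full synthetic dataset per the configured effect structure.

    Species mean outline = base radial-Fourier blob + Brownian coefficient
    deviation + habitat stretch; specimen outline adds the allometric term
    and specimen-level coefficient noise; sides add the asymmetry offset,
    the right side is mirrored; the dense outline is resampled to k
    equidistant landmarks from the fixed landmark and digitization noise is
    added last.
    """
    import pandas as pd

    config.validate()
    rng = np.random.default_rng(config.seed)

    if config.tree_newick is not None:
        tree = read_newick(config.tree_newick)
    else:
        tree = simulate_tree(
            config.n_species, config.birth_rate, seed=int(rng.integers(2**31))
        )
    species = list(tree.tip_names)
    habitats = config.habitat_assignment or _default_habitats(
        species, np.random.default_rng(int(rng.integers(2**31)))
    )
    missing_sp = [s for s in species if s not in habitats]
    if missing_sp:
        raise ValueError(f"habitat_assignment missing species: {missing_sp}")

    dim = config.base_coefficients.size
    # smoothness weights: amplitude of harmonic h scales as 1/h so that
    # random deviations keep the outline smooth (curvature of harmonic h
    # grows as h^2, which would otherwise out-spike the anatomical notch
    # that anchors the fixed landmark)
    harm = np.arange(1, dim // 2 + 1, dtype=float)
    smooth_w = np.concatenate([1.0 / harm, 1.0 / harm])
    bm_dev = simulate_bm_traits(
        tree, dim, config.bm_rate, seed=int(rng.integers(2**31))
    ) * smooth_w

    # unit direction of allometric shape change in coefficient space;
    # harmonics >= 2 only (the h=1 radial terms are near-translations of
    # the curve and are absorbed by Procrustes centering)
    allo_dir = np.zeros(dim)
    allo_dir[1] = 0.8                 # cos 2-theta: elongation
    allo_dir[dim // 2 + 2] = -0.6     # sin 3-theta: triangularity tilt
    allo_dir /= np.linalg.norm(allo_dir)
    # asymmetry direction
    asym_dir = np.zeros(dim)
    asym_dir[2] = 1.0

    delta_by_habitat = {
        "f": config.habitat_effect,
        "b": config.habitat_effect / 2.0,
        "m": 0.0,
    }

    configs = []
    rows = []
    truth_species = {}
    spec_counter = 0
    for si, sp in enumerate(species):
        coeffs = _clamp_coefficients(
            config.base_coefficients + bm_dev[si], rng,
            redraw_sd=np.sqrt(max(config.bm_rate, 1e-8)),
        )
        truth_species[sp] = {
            "mean_coefficients": coeffs.tolist(),
            "habitat": habitats[sp],
        }
        log_sizes = rng.normal(
            config.size_meanlog, config.size_sdlog, config.n_specimens_per_species
        )
        mean_log = log_sizes.mean()
        for j in range(config.n_specimens_per_species):
            spec_counter += 1
            sid = f"{sp}_{j + 1:02d}"
            size = float(np.exp(log_sizes[j]))
            size_term = (
                (log_sizes[j] - mean_log)
                if config.allometry_on_log_size
                else (size - float(np.exp(log_sizes).mean()))
            )
            spec_coeffs = (
                coeffs
                + config.allometry_slope * size_term * allo_dir
                + rng.normal(0.0, config.specimen_coeff_sd, dim) * smooth_w
            )
            one_sided = rng.random() < config.missing_side_fraction
            sides = ["left"] if one_sided else ["left", "right"]
            if one_sided and rng.random() < 0.5:
                sides = ["right"]
            for side in sides:
                sign = 1.0 if side == "left" else -1.0
                side_coeffs = (
                    spec_coeffs
                    + sign * config.side_asymmetry_offset * asym_dir
                    + rng.normal(0.0, config.side_asymmetry_sd, dim) * smooth_w
                )
                dense = _radial_outline(side_coeffs) * size
                dense = _habitat_stretch(dense, delta_by_habitat[habitats[sp]])
                start = _fixed_landmark_start(dense)
                lm = resample_equidistant(
                    OutlinePolyline(dense, closed=True),
                    config.k_landmarks,
                    start,
                    direction="ccw",
                )
                coords = lm.coords + rng.normal(
                    0.0, config.digitization_noise_sd * size,
                    size=lm.coords.shape,
                )
                lm = LandmarkConfiguration(coords, fixed_index=0, side="left")
                if side == "right":
                    # a digitized right opercle is the mirror image
                    lm = reflect(lm)
                configs.append((lm, {"ID": f"{sid}_{side}", "IMAGE": f"{sid}_{side}.jpg"}))
                rows.append(
                    {
                        "specimen_id": sid,
                        "species": sp,
                        "genus": sp.split("_")[0],
                        "side": side,
                        "habitat": habitats[sp],
                        "locality": f"loc{(si % 5) + 1}",
                    }
                )

    classifier = pd.DataFrame(rows)
    newick = tree.to_dendropy().as_string(schema="newick").strip()
    truth = {
        "seed": config.seed,
        "species": truth_species,
        "allometry_direction": allo_dir.tolist(),
        "allometry_slope": config.allometry_slope,
        "habitat_effect": config.habitat_effect,
        "n_specimens": spec_counter,
        "n_one_sided": int(
            classifier.groupby("specimen_id")["side"].count().eq(1).sum()
        ),
    }
    return SimulatedDataset(
        configs=configs,
        classifier=classifier,
        tree=tree,
        newick=newick,
        truth=truth,
    )
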