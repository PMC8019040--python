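"""Synthetic ground-truth inputs: parametric lumen-like meshes and
comparative datasets simulated under known evolutionary parameters.

The tube generator emulates endocast morphology at the level that matters
for complexity analysis: a (possibly tapered) tube whose wall is dented by
smooth invaginations ("folds", optionally spiralling along the axis) and
perturbed by fine band-limited surface noise. Gross concavity (folds) and
fine texture (noise) are controlled independently, so the scale separation
the morphospace is meant to resolve exists by construction. Fold-free,
noise-free specs produce convex capped tubes with a closed-form volume.

The comparative simulator produces pure-birth ultrametric trees and traits
evolved by Brownian motion with a known Pagel lambda and known regression
slopes, for parameter-recovery and calibration testing of the
phylogenetic statistics.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .errors import DomainError
from .mesh_io import SurfaceMesh, validate_mesh
from .phylo_comparative import ComparativeDataset, Phylogeny, _pagel_cov

__all__ = [
    "SyntheticShapeSpec",
    "SimulatedComparativeSpec",
    "make_tube",
    "make_primitive",
    "simulate_tree_and_traits",
    "make_cohort",
    "tube_volume_closed_form",
]


@dataclass
class SyntheticShapeSpec:
    """Parameters of a synthetic endocast-like tube mesh."""

    length: float = 5.0
    radius: float = 1.0
    taper: float = 0.0  # radius shrinks linearly to radius*(1-taper) at the far end
    n_folds: int = 0
    fold_depth: float = 0.0  # fraction of local radius, in [0, 0.9]
    fold_width: float = 0.45  # angular half-width of a fold, radians
    spiral_turns: float = 0.0  # helical twist of fold loci over the length
    surface_noise_amplitude: float = 0.0  # fraction of local radius
    noise_modes: tuple[int, int] = (9, 18)  # band of angular/axial harmonics
    resolution: tuple[int, int] = (128, 256)  # angular x axial vertices
    seed: int = 0


@dataclass
class SimulatedComparativeSpec:
    """Parameters of a simulated tree + trait dataset."""

    n_species: int = 19
    birth_rate: float = 1.0
    lambda_: float = 1.0
    slopes: dict = field(default_factory=dict)  # predictor name -> true slope
    residual_sd: float = 1.0
    predictor_names: tuple[str, ...] = ()
    seed: int = 0


def tube_volume_closed_form(spec: SyntheticShapeSpec) -> float:
    """Analytic volume of the fold-free, noise-free (possibly tapered) tube.

    Integrates pi * r(z)^2 over the axis for the linearly tapered radius;
    valid only when n_folds == 0 and surface_noise_amplitude == 0.
    """
    if spec.n_folds or spec.surface_noise_amplitude:
        raise DomainError("closed form only valid for fold-free, noise-free tubes")
    r0 = spec.radius
    r1 = spec.radius * (1.0 - spec.taper)
    return float(np.pi * spec.length * (r0 * r0 + r0 * r1 + r1 * r1) / 3.0)


def _fold_field(theta: np.ndarray, z01: np.ndarray, spec: SyntheticShapeSpec) -> np.ndarray:
    """Total relative dent depth at (theta, z), capped below self-intersection.

    Each fold is a raised-cosine bump in angular distance from its
    (possibly spiralling) locus, faded in over the first/last 15% of the
    axis so the end caps stay clean.
    """
    if spec.n_folds == 0 or spec.fold_depth == 0.0:
        return np.zeros_like(theta)
    axial = np.clip(np.minimum(z01, 1.0 - z01) / 0.15, 0.0, 1.0)
    axial = 0.5 * (1.0 - np.cos(np.pi * axial))
    dent = np.zeros_like(theta)
    phase = 2.0 * np.pi * spec.spiral_turns * z01
    for i in range(spec.n_folds):
        center = 2.0 * np.pi * i / spec.n_folds + phase
        d = np.angle(np.exp(1j * (theta - center)))  # wrapped angular distance
        inside = np.abs(d) < spec.fold_width
        bump = np.where(inside, 0.5 * (1.0 + np.cos(np.pi * d / spec.fold_width)), 0.0)
        dent += spec.fold_depth * bump
    return np.minimum(dent * axial, 0.95)


def _noise_field(theta: np.ndarray, z01: np.ndarray, spec: SyntheticShapeSpec) -> np.ndarray:
    """Band-limited smooth radial noise, zero at the tube ends, unit scale."""
    if spec.surface_noise_amplitude == 0.0:
        return np.zeros_like(theta)
    rng = np.random.default_rng(spec.seed + 777)
    lo, hi = spec.noise_modes
    out = np.zeros_like(theta)
    n_terms = 6
    for _ in range(n_terms):
        m = int(rng.integers(lo, hi + 1))
        nz = int(rng.integers(lo, hi + 1))
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        out += np.cos(m * theta + ph1) * np.cos(np.pi * nz * z01 + ph2)
    out /= np.sqrt(n_terms / 2.0)  # approximately unit variance
    fade = np.clip(np.minimum(z01, 1.0 - z01) / 0.1, 0.0, 1.0)
    return out * fade


def make_tube(spec: SyntheticShapeSpec) -> SurfaceMesh:
    """Generate a watertight tube mesh from a shape spec (deterministic)."""
    if spec.fold_depth >= 1.0 or spec.fold_depth < 0.0:
        raise DomainError("fold_depth must lie in [0, 1) (self-intersection)")
    if not (0.0 <= spec.taper < 1.0):
        raise DomainError("taper must lie in [0, 1)")
    n_theta, n_z = spec.resolution
    if n_theta < 8 or n_z < 4:
        raise DomainError("resolution too low for a closed tube")
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    z01 = np.linspace(0.0, 1.0, n_z)
    T, Z = np.meshgrid(theta, z01, indexing="ij")  # (n_theta, n_z)
    base_r = spec.radius * (1.0 - spec.taper * Z)
    r = base_r * (1.0 - _fold_field(T, Z, spec))
    r = r + spec.surface_noise_amplitude * base_r * _noise_field(T, Z, spec)
    r = np.maximum(r, 0.02 * spec.radius)

    x = r * np.cos(T)
    y = r * np.sin(T)
    z = spec.length * Z
    ring = np.stack([x, y, z], axis=-1).reshape(n_theta * n_z, 3)
    c0 = np.array([[0.0, 0.0, 0.0]])
    c1 = np.array([[0.0, 0.0, spec.length]])
    vertices = np.concatenate([ring, c0, c1])
    i_c0 = n_theta * n_z
    i_c1 = i_c0 + 1

    def vid(it: np.ndarray, iz: np.ndarray) -> np.ndarray:
        return it * n_z + iz

    it = np.arange(n_theta)
    itn = (it + 1) % n_theta
    faces = []
    for iz in range(n_z - 1):
        a = vid(it, iz)
        b = vid(itn, iz)
        c = vid(itn, iz + 1)
        d = vid(it, iz + 1)
        faces.append(np.stack([a, b, c], axis=1))
        faces.append(np.stack([a, c, d], axis=1))
    # caps: bottom fan wound to face -z, top fan to face +z
    faces.append(np.stack([np.full(n_theta, i_c0), vid(itn, 0), vid(it, 0)], axis=1))
    faces.append(
        np.stack([np.full(n_theta, i_c1), vid(it, n_z - 1), vid(itn, n_z - 1)], axis=1)
    )
    mesh = validate_mesh(
        vertices, np.concatenate(faces), units="mm",
        name=f"tube_d{spec.fold_depth:g}_n{spec.n_folds}_s{spec.seed}",
    )
    return mesh


def make_primitive(kind: str, size: float = 1.0, resolution: int = 4) -> SurfaceMesh:
    """Watertight primitive with a known analytic volume.

    kind: "sphere" (radius=size), "cube" (edge=size), "torus"
    (R=size, r=size/4), or "regular_tetrahedron" (edge=size).
    """
    import trimesh

    if kind == "sphere":
        tm = trimesh.creation.icosphere(subdivisions=resolution, radius=size)
    elif kind == "cube":
        tm = trimesh.creation.box(extents=(size, size, size))
    elif kind == "torus":
        sec = max(32, 24 * resolution)
        tm = trimesh.creation.torus(
            major_radius=size, minor_radius=size / 4.0,
            major_sections=sec, minor_sections=sec // 2,
        )
    elif kind == "regular_tetrahedron":
        v = size * np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        ) / np.sqrt(8.0)  # edge length = size
        f = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
        return validate_mesh(v, f, name="regular_tetrahedron")
    else:
        raise DomainError(f"unknown primitive kind {kind!r}")
    return validate_mesh(np.asarray(tm.vertices), np.asarray(tm.faces), name=kind)


# ---------------------------------------------------------------------------
# comparative simulation
# ---------------------------------------------------------------------------


def simulate_pure_birth_tree(n_species: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """Ultrametric pure-birth (Yule) tree with tips s01..sNN."""
    from dendropy.simulate import treesim

    rng = _random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rng,
    )
    # the simulator stops exactly at the n-th speciation, leaving a
    # zero-length cherry; run the clock on to just before the next event
    extra = rng.expovariate(n_species * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    width = max(2, len(str(n_species)))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"s{i + 1:0{width}d}"
    return Phylogeny(tree)


def simulate_tree_and_traits(
    spec: SimulatedComparativeSpec,
) -> tuple[Phylogeny, ComparativeDataset]:
    """Simulate a tree, BM predictors, and a response with known structure.

    response = sum(beta_j * predictor_j) + residual, where the residual is
    multivariate normal with Pagel-lambda-scaled BM covariance (unit-depth
    scaled) times residual_sd^2. Deterministic per seed.
    """
    if spec.n_species < 4:
        raise DomainError("need at least 4 species")
    if not (0.0 <= spec.lambda_ <= 1.0):
        raise DomainError("lambda must lie in [0, 1]")
    phy = simulate_pure_birth_tree(spec.n_species, spec.birth_rate, spec.seed)
    labels, C = phy.covariance()
    n = len(labels)
    depth = float(np.diag(C).mean())
    Cn = C / depth  # unit-depth scaling so residual_sd is on trait scale
    rng = np.random.default_rng(spec.seed)
    L_bm = np.linalg.cholesky(Cn + 1e-12 * np.eye(n))

    names = list(spec.predictor_names) or list(spec.slopes.keys())
    data = {}
    y = np.zeros(n)
    for name in names:
        x = L_bm @ rng.standard_normal(n)
        data[name] = x
        y = y + spec.slopes.get(name, 0.0) * x
    V = _pagel_cov(Cn, spec.lambda_)
    Lv = np.linalg.cholesky(V + 1e-12 * np.eye(n))
    y = y + spec.residual_sd * (Lv @ rng.standard_normal(n))
    data["response"] = y
    traits = pd.DataFrame(data, index=pd.Index(labels, name="species"))
    return phy, ComparativeDataset(traits=traits, tree=phy, log10=())


def _clades(n_species: int, rng: np.random.Generator) -> np.ndarray:
    """Clade labels echoing the study's 14/4/1 cetacean-heavy composition."""
    n_sir = 1 if n_species >= 6 else 0
    n_pin = min(4, max(1, round(n_species / 4.75))) if n_species >= 4 else 0
    n_cet = n_species - n_pin - n_sir
    labels = ["cetacean"] * n_cet + ["pinniped"] * n_pin + ["sirenian"] * n_sir
    return rng.permutation(labels)


def make_cohort(
    n_species: int = 19,
    n_specimens: int = 40,
    seed: int = 0,
    resolution: tuple[int, int] = (96, 160),
) -> tuple[list[tuple[str, str, SyntheticShapeSpec]], Phylogeny, ComparativeDataset]:
    """A study-shaped cohort: specimen shape specs, tree and trait table.

    Species get distinct gross-complexity levels (fold count/depth) and
    fine-texture levels; specimens within a species jitter around the
    species spec, so within-species complexity spread is smaller than
    between-species spread by construction. Trait columns mirror the
    comparative schema (body lengths, testes mass, dimorphism, penis-tip
    category); they are simulated and carry no planted association with
    shape complexity unless requested downstream.
    """
    if n_specimens < n_species:
        raise DomainError("need at least one specimen per species")
    rng = np.random.default_rng(seed)
    phy = simulate_pure_birth_tree(n_species, seed=seed)
    species = phy.tip_labels

    depth_levels = np.linspace(0.0, 0.8, n_species)
    rng.shuffle(depth_levels)
    noise_levels = rng.uniform(0.0, 0.04, size=n_species)
    base_specs = {
        sp: SyntheticShapeSpec(
            length=5.0,
            radius=1.0,
            taper=float(rng.uniform(0.0, 0.3)),
            n_folds=int(rng.integers(3, 7)) if depth_levels[i] > 0 else 0,
            fold_depth=float(depth_levels[i]),
            spiral_turns=float(rng.uniform(0.0, 1.5)),
            surface_noise_amplitude=float(noise_levels[i]),
            resolution=resolution,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for i, sp in enumerate(species)
    }
    # one specimen per species, remainder distributed at random
    owners = list(species) + [
        species[i] for i in rng.integers(0, n_species, size=n_specimens - n_species)
    ]
    specimens = []
    for j, sp in enumerate(owners):
        base = base_specs[sp]
        jit = replace(
            base,
            fold_depth=float(np.clip(base.fold_depth * rng.uniform(0.92, 1.08), 0.0, 0.9)),
            surface_noise_amplitude=float(
                base.surface_noise_amplitude * rng.uniform(0.9, 1.1)
            ),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        specimens.append((f"{sp}_spec{j:02d}", sp, jit))

    labels, C = phy.covariance()
    depth = float(np.diag(C).mean())
    L = np.linalg.cholesky(C / depth + 1e-12 * np.eye(n_species))
    bm = lambda: L @ rng.standard_normal(n_species)  # noqa: E731
    traits = pd.DataFrame(
        {
            "neonate_length": 10 ** (0.8 + 0.2 * bm()),
            "mother_length": 10 ** (2.0 + 0.2 * bm()),
            "testes_mass": 10 ** (2.5 + 0.4 * bm()),
            "male_body_mass": 10 ** (4.0 + 0.3 * bm()),
            "ssd": 10 ** (0.02 + 0.05 * bm()),
            "penis_tip": rng.choice(["filiform", "tapered", "blunt-end"], size=n_species),
            "clade": _clades(n_species, rng),
        },
        index=pd.Index(labels, name="species"),
    )
    dataset = ComparativeDataset(
        traits=traits,
        tree=phy,
        log10=("neonate_length", "mother_length", "testes_mass", "male_body_mass", "ssd"),
    )
    return specimens, phy, dataset
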