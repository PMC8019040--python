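"""End-to-end orchestration: specimen runs and cohort analyses.

A specimen run executes fill -> downsample -> l_ref -> characteristic
curve -> optimal refinement -> heatmap -> multi-scale profile with seeds
derived from a master seed by fixed stage offsets, and writes JSON/CSV/PLY
outputs plus a provenance record (config hash, seeds, counts).
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alpha_engine import (
    CharacteristicCurve,
    ComplexityResult,
    _engine,
    characteristic_curve,
    default_k_grid,
    optimal_refinement,
)
from .errors import DomainError, LabelMappingError
from .heatmap import HeatmapMesh, build_heatmap, coarsest_contribution
from .mesh_io import SurfaceMesh, read_mesh, write_heatmap_mesh
from .morphospace import pca, phylo_pca, sample_profile
from .phylo_comparative import (
    ComparativeDataset,
    Phylogeny,
    pagels_lambda,
    ancestral_states,
    pgls,
    phyl_anova,
    phyl_manova,
)
from .point_cloud import downsample, fill_interior, reference_length

__all__ = ["RunConfig", "SpecimenResult", "run_specimen", "run_cohort"]

_STAGE_OFFSETS = {"fill": 1, "downsample": 2, "anova": 3, "manova": 4}


@dataclass
class RunConfig:
    """Tunable parameters of a pipeline run (defaults are the study protocol)."""

    fill_min: int = 250_000
    downsample_target: int = 100_000
    n_neighbors: int = 100
    k_min: float = 0.1
    k_max: float = 10_000.0
    k_steps: int = 200
    n_sampled: int = 6
    tol: float = 1e-3
    seed: int = 0
    subset: str = "all"  # all | cetaceans
    heatmap: bool = True

    def __post_init__(self):
        if min(self.fill_min, self.downsample_target, self.n_neighbors,
               self.k_steps, self.n_sampled) <= 0:
            raise DomainError("all counts must be positive")
        if not (0 < self.k_min < self.k_max):
            raise DomainError("need 0 < k_min < k_max")
        if self.downsample_target > self.fill_min:
            raise DomainError("downsample_target cannot exceed fill_min")
        if self.subset not in ("all", "cetaceans"):
            raise DomainError("subset must be 'all' or 'cetaceans'")

    def k_grid(self) -> np.ndarray:
        return default_k_grid(self.k_min, self.k_max, self.k_steps)

    def sampled_k(self) -> np.ndarray:
        return np.logspace(np.log10(self.k_min), np.log10(self.k_max), self.n_sampled)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def stage_seed(self, stage: str, specimen_id: str | None = None) -> int:
        base = self.seed * 1000 + _STAGE_OFFSETS.get(stage, 0)
        if specimen_id is not None:
            base += zlib.crc32(specimen_id.encode()) % 100_000
        return base % (2**31 - 1)


@dataclass
class SpecimenResult:
    specimen_id: str
    complexity: ComplexityResult
    curve: CharacteristicCurve
    profile: object
    heatmap: HeatmapMesh | None
    provenance: dict

    def to_json_dict(self) -> dict:
        return {
            "specimen_id": self.specimen_id,
            "l_ref": self.curve.l_ref,
            "mesh_volume": self.curve.mesh_volume,
            "optimal_k": self.complexity.optimal_k,
            "alpha_complexity": self.complexity.alpha_complexity,
            "in_range": self.complexity.in_range,
            "diagnostics": _jsonify(self.complexity.diagnostics),
            "provenance": self.provenance,
        }


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_specimen(
    mesh: SurfaceMesh | str | Path,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    specimen_id: str | None = None,
) -> SpecimenResult:
    """Full single-specimen analysis; deterministic given the config seed."""
    config = config or RunConfig()
    if not isinstance(mesh, SurfaceMesh):
        mesh = read_mesh(mesh)
    sid = specimen_id or mesh.name or "specimen"

    raw = fill_interior(mesh, n_min=config.fill_min,
                        seed=config.stage_seed("fill", sid))
    cloud = downsample(raw, n_target=config.downsample_target,
                       seed=config.stage_seed("downsample", sid))
    cloud.source_mesh_id = sid
    reference_length(cloud, n_neighbors=config.n_neighbors)
    k_grid = config.k_grid()
    curve = characteristic_curve(cloud, mesh, k_grid)
    result = optimal_refinement(curve, cloud, mesh, tol=config.tol)
    profile = sample_profile(curve, config.sampled_k())

    hm = None
    if config.heatmap:
        coarsest = coarsest_contribution(cloud, k_grid)
        # a boundary (convex) result sits at the grid top, whose fit is the hull
        alpha_opt = (
            np.inf if result.optimal_k >= k_grid[-1] else result.optimal_k * curve.l_ref
        )
        opt_fit = _engine(cloud).fit(alpha_opt, k=result.optimal_k)
        hm = build_heatmap(opt_fit, coarsest, cloud, k_grid)

    provenance = {
        "config_hash": config.hash(),
        "master_seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s, sid) for s in ("fill", "downsample")},
        "n_raw": raw.n_raw,
        "n_down": cloud.n_down,
        "n_vertices": mesh.n_vertices,
        "n_faces": mesh.n_faces,
    }
    out = SpecimenResult(sid, result, curve, profile, hm, provenance)
    if out_dir is not None:
        _write_specimen(out, Path(out_dir))
    return out


def _write_specimen(res: SpecimenResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = res.specimen_id
    res.curve.to_frame().to_csv(out_dir / f"{sid}_curve.csv", index=False)
    res.profile.to_series().to_frame().T.to_csv(out_dir / f"{sid}_profile.csv")
    with open(out_dir / f"{sid}_result.json", "w") as fh:
        json.dump(res.to_json_dict(), fh, indent=2, sort_keys=True)
    if res.heatmap is not None:
        write_heatmap_mesh(res.heatmap, out_dir / f"{sid}_heatmap.ply")


def run_cohort(
    specimens: list,
    tree: Phylogeny,
    dataset: ComparativeDataset,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Cohort analysis over (specimen_id, species, mesh-or-spec) entries.

    Per-specimen pipelines feed an all-individuals PCA and species-mean
    PCA/pPCA of the multi-scale profiles, a Pagel-lambda signal test and
    ancestral states for alpha complexity, PGLS models for the standard
    predictor sets, and phylogenetic ANOVA/MANOVA over penis-tip classes.
    """
    from .synthetic_data import SyntheticShapeSpec, make_tube

    config = config or RunConfig()
    traits = dataset.traits
    if config.subset == "cetaceans":
        if "clade" not in traits.columns:
            raise LabelMappingError("subset='cetaceans' needs a 'clade' trait column")
        keep = set(traits.index[traits["clade"] == "cetacean"].astype(str))
        specimens = [s for s in specimens if s[1] in keep]
        traits = traits.loc[sorted(keep)]
    species_used = sorted({sp for _, sp, _ in specimens})
    missing = set(species_used) - set(traits.index.astype(str))
    if missing:
        raise LabelMappingError(f"manifest species missing from traits: {sorted(missing)}")

    per_specimen = {}
    for sid, sp, obj in specimens:
        if isinstance(obj, SyntheticShapeSpec):
            mesh = make_tube(obj)
        elif isinstance(obj, SurfaceMesh):
            mesh = obj
        else:
            mesh = read_mesh(obj)
        res = run_specimen(mesh, config=config, out_dir=out_dir, specimen_id=sid)
        per_specimen[sid] = (sp, res)

    prof = pd.DataFrame(
        {sid: r.profile.to_series() for sid, (_, r) in per_specimen.items()}
    ).T
    complexity = pd.Series(
        {sid: r.complexity.alpha_complexity for sid, (_, r) in per_specimen.items()},
        name="alpha_complexity",
    )
    species_of = pd.Series({sid: sp for sid, (sp, _) in per_specimen.items()})
    prof_species = prof.groupby(species_of).mean()
    cx_species = complexity.groupby(species_of).mean()

    tree_used = tree.pruned_to(sorted(prof_species.index)) if set(
        prof_species.index
    ) != set(tree.tip_labels) else tree

    # a refinement scale can be degenerate at low sampling density (e.g.
    # no tetrahedron survives the finest alpha in any specimen); such
    # columns carry no information and are dropped from the ordinations
    keep_cols = prof.columns[prof.std(axis=0, ddof=1) > 0]
    if len(keep_cols) < len(prof.columns):
        import warnings

        warnings.warn(
            f"dropping constant profile column(s) "
            f"{sorted(set(prof.columns) - set(keep_cols))} from the PCA",
            stacklevel=2,
        )
    prof_pca = prof[keep_cols]
    prof_species_pca = prof_species[keep_cols]

    out = {
        "complexity": complexity,
        "species_complexity": cx_species,
        "profiles": prof,
        "pca_all": pca(prof_pca),
        "pca_species": pca(prof_species_pca),
        "ppca": phylo_pca(prof_species_pca, tree_used),
        "lambda": pagels_lambda(tree_used, cx_species),
        "ancestral": ancestral_states(tree_used, cx_species),
    }

    model_data = traits.copy()
    model_data = model_data.join(cx_species.rename("alpha_complexity"), how="inner")
    ds = ComparativeDataset(traits=model_data, tree=tree_used, log10=dataset.log10)
    predictor_sets = {
        "neonate": ["neonate_length", "mother_length"],
        "testes": ["testes_mass", "male_body_mass"],
        "ssd": ["ssd"],
    }
    models = {}
    for name, preds in predictor_sets.items():
        if all(p in model_data.columns for p in preds):
            models[name] = pgls(ds, response="alpha_complexity", predictors=preds)
    out["pgls"] = models

    if "penis_tip" in model_data.columns and model_data["penis_tip"].nunique() > 1:
        out["anova"] = phyl_anova(
            tree_used, cx_species, model_data["penis_tip"],
            n_sim=1000, seed=config.stage_seed("anova"),
        )
        n_pc = min(3, out["pca_species"].scores.shape[1],
                   len(cx_species) - model_data["penis_tip"].nunique())
        if n_pc >= 1:
            sp_scores = out["pca_species"].scores.iloc[:, :n_pc]
            out["manova"] = phyl_manova(
                tree_used, sp_scores, model_data["penis_tip"],
                n_sim=1000, seed=config.stage_seed("manova"),
            )

    if out_dir is not None:
        _write_cohort(out, Path(out_dir))
    return out


def _write_cohort(out: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    out["complexity"].to_csv(out_dir / "complexity.csv")
    out["species_complexity"].to_csv(out_dir / "species_complexity.csv")
    out["profiles"].to_csv(out_dir / "profiles.csv")
    for key in ("pca_all", "pca_species", "ppca"):
        res = out[key]
        res.scores.to_csv(out_dir / f"{key}_scores.csv")
        res.loadings.to_csv(out_dir / f"{key}_loadings.csv")
        res.variance_explained.to_csv(out_dir / f"{key}_variance.csv")
    rows = []
    for name, fit in out.get("pgls", {}).items():
        for term, r in fit.coef.iterrows():
            rows.append(
                {"model": name, "predictor": term, "slope": r["slope"],
                 "se": r["se"], "t": r["t"], "p": r["p"], "lambda": fit.lambda_}
            )
    if rows:
        pd.DataFrame(rows).to_csv(out_dir / "pgls_models.csv", index=False)
    summary = {"lambda": out["lambda"].lambda_, "lambda_p": out["lambda"].p_value}
    if "anova" in out:
        summary.update({"anova_F": out["anova"].F, "anova_p_phylo": out["anova"].p_phylo})
    if "manova" in out:
        summary.update(
            {"manova_wilks": out["manova"].wilks, "manova_p_phylo": out["manova"].p_phylo}
        )
    with open(out_dir / "comparative_summary.json", "w") as fh:
        json.dump(_jsonify(summary), fh, indent=2, sort_keys=True)
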