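"""End-to-end orchestration of the mutagenesis-trial analysis.

``run_pipeline`` drives the full workflow: simulate germination, exclude
over-severe doses, simulate the generations with truncation selection,
summarize genetic parameters and Duncan groupings per generation, account
genetic gains and their between-generation improvement, run the
correlation/path and multivariate stages, and write every artifact (CSV,
Newick, plain-text tables) plus a manifest with content hashes so a rerun
with the same config and seed is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .association import PathAnalysis, spearman_matrix
from .design import (
    PATH_PREDICTORS,
    SimParams,
    TrialDesign,
    YIELD_TRAIT,
    design_from_dict,
    params_from_dict,
)
from .genetics import DEFAULT_K, population_summary
from .io import render_summary, write_trait_csv
from .multivariate import (
    PopulationPCA,
    cluster_profiles,
    euclidean_matrix,
    population_means,
    upgma,
)
from .selection import gain_delta, genetic_gain, select_top
from .simulate import (
    SelectionRule,
    apply_dose_exclusion,
    simulate_generations,
    simulate_germination,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Everything a full run needs; every field has a documented default."""

    design: TrialDesign = field(default_factory=TrialDesign)
    params: SimParams = field(default_factory=SimParams)
    seed: int = 0
    out_dir: str = "breedvar-run"
    alpha: float = 0.05  #: significance level for ANOVA/DMRT
    k: float = DEFAULT_K  #: selection-intensity constant for GA
    selection_trait: str = YIELD_TRAIT
    selection_n: int = 30  #: lines kept per treatment when advancing
    selection_start: str = "M2"  #: generation whose advancement is first selected
    analysis_generations: tuple[str, ...] = ("M2", "M3")
    cluster_k: int = 5  #: flat clusters cut from the dendrogram
    standardize_distances: bool = False
    correlation_level: str = "line"
    path_predictors: tuple[str, ...] = PATH_PREDICTORS

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for gen in self.analysis_generations:
            if gen not in self.design.generations:
                raise ValueError(f"analysis generation {gen!r} not in design")

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        allowed = {f.name for f in fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "design" in data and not isinstance(data["design"], TrialDesign):
            data["design"] = design_from_dict(data["design"])
        if "params" in data and not isinstance(data["params"], SimParams):
            data["params"] = params_from_dict(data["params"])
        for key in ("analysis_generations", "path_predictors"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def selection_rule(self) -> SelectionRule:
        return SelectionRule(
            trait=self.selection_trait,
            n=self.selection_n,
            start_generation=self.selection_start,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Execute the full workflow; returns the run directory.

    Any stage failure is re-raised with the stage name prepended.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    t0 = time.perf_counter()
    written: list[Path] = []

    def save_csv(frame: pd.DataFrame, name: str, **kwargs) -> None:
        path = out / name
        frame.to_csv(path, **kwargs)
        written.append(path)

    def save_text(text: str, name: str) -> None:
        path = out / name
        path.write_text(text, encoding="utf-8")
        written.append(path)

    design, params = config.design, config.params
    try:
        stage = "simulate-germination"
        germ = simulate_germination(design, params, seed=config.seed)
        save_csv(germ, "germination.csv", index=False)

        stage = "exclude-doses"
        retained = apply_dose_exclusion(germ, design.control_label)
        save_text("\n".join(retained) + "\n", "retained_treatments.txt")
        logger.info("%s: retained %d of %d treatments", stage, len(retained),
                    len(design.treatments))

        stage = "simulate-generations"
        table = simulate_generations(
            design, params, selection_rule=config.selection_rule(),
            seed=config.seed, treatments=retained,
        )
        write_trait_csv(table, out / "traits.csv")
        written.append(out / "traits.csv")

        stage = "genetics-dmrt"
        summaries = {}
        for gen in config.analysis_generations:
            for variety in design.varieties:
                summ = population_summary(
                    table, variety, gen, alpha=config.alpha, k=config.k
                )
                summaries[(variety, gen)] = summ
                slug = f"{_slug(variety)}_{gen}"
                save_csv(summ, f"summary_{slug}.csv", index=False)
                save_text(render_summary(summ), f"summary_{slug}.txt")

        stage = "selection"
        first_gen = config.analysis_generations[0]
        for variety in design.varieties:
            sel = select_top(
                table, variety, first_gen, trait=config.selection_trait,
                n=config.selection_n,
                treatments=[t for t in retained if t != design.control_label],
            )
            frame = pd.DataFrame(
                [
                    (t, rank + 1, line)
                    for t, lines in sel.selected.items()
                    for rank, line in enumerate(lines)
                ],
                columns=["treatment", "rank", "line"],
            )
            save_csv(frame, f"selected_{_slug(variety)}_{first_gen}.csv", index=False)

        stage = "genetic-gain"
        for variety in design.varieties:
            reports = {}
            for gen in config.analysis_generations:
                rep = genetic_gain(
                    table, variety, gen, control_label=design.control_label,
                    trait=YIELD_TRAIT,
                )
                reports[gen] = rep
                save_csv(rep.table, f"gain_{_slug(variety)}_{gen}.csv")
            if len(config.analysis_generations) >= 2:
                g0, g1 = config.analysis_generations[:2]
                delta = gain_delta(reports[g0], reports[g1])
                save_csv(delta, f"gain_delta_{_slug(variety)}.csv")
                logger.info(
                    "%s %s->%s: largest gain improvement in %s", variety, g0, g1,
                    delta.attrs["argmax"],
                )

        stage = "correlation-path"
        last_gen = config.analysis_generations[-1]
        for variety in design.varieties:
            corr = spearman_matrix(
                table[(table["variety"] == variety)
                      & (table["generation"] == last_gen)],
                level=config.correlation_level,
            )
            save_csv(corr.rho, f"correlation_{_slug(variety)}.csv")
            save_csv(corr.stars, f"correlation_stars_{_slug(variety)}.csv")
            wide = (
                table[(table["variety"] == variety)
                      & (table["generation"] == last_gen)]
                .groupby(["treatment", "line", "trait"])["value"].mean()
                .unstack("trait")
            )
            pa = PathAnalysis().fit(
                wide[list(config.path_predictors)], wide[YIELD_TRAIT]
            )
            path_out = pd.DataFrame(
                {"direct": pa.direct_effects_, "r_iy": pa.total_correlations_}
            )
            path_out.attrs["residual"] = pa.residual_
            save_csv(path_out, f"path_{_slug(variety)}.csv")
            save_csv(pa.indirect_effects_, f"path_indirect_{_slug(variety)}.csv")

        stage = "multivariate"
        mv_gen = config.analysis_generations[0]
        for variety in design.varieties:
            means = population_means(table, variety, mv_gen)
            dmat = euclidean_matrix(means, standardize=config.standardize_distances)
            dend = upgma(dmat)
            k = min(config.cluster_k, len(means))
            membership, profiles, inter = cluster_profiles(dend, k, means, dmat)
            pca_fit = PopulationPCA().fit(means)
            slug = _slug(variety)
            save_csv(means, f"means_{slug}_{mv_gen}.csv")
            save_csv(dmat, f"distances_{slug}.csv")
            save_text(dend.to_newick() + "\n", f"dendrogram_{slug}.nwk")
            save_csv(membership.to_frame(), f"clusters_{slug}.csv")
            save_csv(profiles, f"cluster_profiles_{slug}.csv")
            save_csv(inter, f"cluster_distances_{slug}.csv")
            save_csv(
                pd.DataFrame(
                    {
                        "eigenvalue": pca_fit.eigenvalues_,
                        "explained_pct": pca_fit.explained_pct_.to_numpy(),
                    },
                    index=pca_fit.explained_pct_.index,
                ),
                f"pca_eigen_{slug}.csv",
            )
            save_csv(pca_fit.scores_, f"pca_scores_{slug}.csv")
            save_csv(pca_fit.cos2_, f"pca_cos2_{slug}.csv")
            save_csv(pca_fit.contributions_, f"pca_contributions_{slug}.csv")

        stage = "manifest"
        manifest = {
            "package": "breedvar",
            "version": __version__,
            "seed": config.seed,
            "alpha": config.alpha,
            "k": config.k,
            "varieties": list(design.varieties),
            "retained_treatments": retained,
            "retained_populations_per_variety": len(retained),
            "generations": list(design.generations),
            "artifacts": {
                p.name: _sha256(p) for p in sorted(written, key=lambda p: p.name)
            },
        }
        # wall time is logged, not written: the manifest must be byte-identical
        # across reruns with the same config and seed
        logger.info("pipeline finished in %.2f s", time.perf_counter() - t0)
        save_text(json.dumps(manifest, indent=2) + "\n", "manifest.json")
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def _slug(text: str) -> str:
    return "".join(c.lower() if c.isalnum() else "-" for c in text).strip("-")


def config_to_yaml_template() -> str:
    """A commented YAML template with every option at its default."""
    cfg = RunConfig()
    doc = {
        "seed": cfg.seed,
        "out_dir": cfg.out_dir,
        "alpha": cfg.alpha,
        "k": cfg.k,
        "selection_trait": cfg.selection_trait,
        "selection_n": cfg.selection_n,
        "selection_start": cfg.selection_start,
        "analysis_generations": list(cfg.analysis_generations),
        "cluster_k": cfg.cluster_k,
        "standardize_distances": cfg.standardize_distances,
        "correlation_level": cfg.correlation_level,
        "path_predictors": list(cfg.path_predictors),
        "design": {
            "seeds_per_treatment": cfg.design.seeds_per_treatment,
            "replications": cfg.design.replications,
            "lines_per_treatment": cfg.design.lines_per_treatment,
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)
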