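"""Config-driven orchestration of the full analysis chain.

Stages: rarefy -> alpha diversity -> abundance classification (+ truncation
robustness) -> Bray-Curtis / NMDS / ANOSIM -> Mantel tables per category ->
PCNM + VIF + forward selection + variation partitioning -> neutral-model
fits per subset.  Every stage writes TSV/JSON outputs into the run directory
and derives its random seed deterministically from the run seed, so reruns
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import DEFAULT_FRACTIONS, classify_otus, combine_dominant, multicola
from .beta import anosim, bray_curtis, nmds
from .metadata import SampleMetadata, read_metadata
from .neutral import fit_ncm, occurrence_frequency
from .otu import OtuTable, alpha_diversity, rarefy, read_otu_table, write_otu_table
from .spatial import distance_decay, env_distance, geographic_distance, mantel, pcnm
from .varpart import forward_select, varpart2, vif_filter

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_pipeline", "generate_fixtures"]

CATEGORY_SETS = ("all", "dominant", "RT", "CRT")


@dataclass
class AnalysisConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    otu_table: str
    metadata: str
    depth: int | None = None            # default: minimum sample total
    rare_thresh: float = 1e-4
    abund_thresh: float = 1e-2
    exclude: list[str] = field(default_factory=list)
    n_permutations: int = 999
    seed: int = 0
    multicola_fractions: list[float] = field(default_factory=lambda: list(DEFAULT_FRACTIONS))
    nmds_restarts: int = 20
    forward_selection: bool = True
    alpha: float = 0.05

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1, allow_nan=True,
                               default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage_seed(base: int, stage: str) -> int:
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big")


def _category_tables(table: OtuTable, assignment) -> dict[str, OtuTable]:
    out = {"all": table}
    sets = {
        "dominant": combine_dominant(assignment),
        "RT": assignment.otus_in("RT"),
        "CRT": assignment.otus_in("CRT"),
    }
    for name, otus in sets.items():
        if len(otus) >= 2:
            sub = table.select_otus(otus)
            if (sub.sample_totals() > 0).all():
                out[name] = sub
    return out


def _predictors_for(name, selected, fallback, n, note):
    """Selected variables if any; otherwise the VIF-retained set truncated to
    keep the model estimable."""
    if selected:
        return selected
    cap = max(1, n - 3)
    note.append(f"{name}: forward selection empty; using VIF-retained set")
    return fallback[:cap]


def run_pipeline(config: AnalysisConfig, outdir) -> dict:
    """Execute every stage and write the report bundle into ``outdir``.

    Returns a dict of the stage summaries.  A failing stage raises with the
    stage name; outputs written up to that point are preserved.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load_inputs"
    try:
        table = read_otu_table(config.otu_table)
        metadata = read_metadata(config.metadata)
        manifest = {
            "version": __version__,
            "config": asdict(config),
            "inputs": {
                "otu_table": {"path": str(config.otu_table), "sha256": _sha256(config.otu_table)},
                "metadata": {"path": str(config.metadata), "sha256": _sha256(config.metadata)},
            },
        }
        if config.exclude:
            keep = [s for s in table.sample_ids if s not in set(config.exclude)]
            table = table.select_samples(keep)
        metadata = metadata.select(table.sample_ids)
        habitats = sorted(set(metadata.habitat))

        stage = "rarefy"
        depth = config.depth or int(table.sample_totals().min())
        rarefied = rarefy(table, depth, _stage_seed(config.seed, "rarefy")).drop_empty_otus()
        write_otu_table(rarefied, out / "rarefied.tsv")
        manifest["rarefaction"] = {"depth": depth,
                                   "seed": _stage_seed(config.seed, "rarefy"),
                                   "n_samples": rarefied.n_samples,
                                   "n_otus": rarefied.n_otus}

        stage = "alpha_diversity"
        alpha = alpha_diversity(rarefied)
        alpha.index.name = "sample_id"
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")

        stage = "classification"
        assignment = classify_otus(rarefied, config.rare_thresh, config.abund_thresh)
        assignment.write(out / "categories.tsv")
        profile = multicola(rarefied, config.multicola_fractions,
                            seed=_stage_seed(config.seed, "multicola"))
        profile.write(out / "multicola.tsv")
        classification = {"category_counts": assignment.counts(),
                          "n_dominant": len(combine_dominant(assignment)),
                          "multicola_flagged": profile.flagged}
        _write_json(out / "classification.json", classification)

        stage = "beta_diversity"
        bc = bray_curtis(rarefied)
        bc.write(out / "bray_curtis.tsv")
        ord_res = nmds(bc, k=2, n_restarts=config.nmds_restarts,
                       seed=_stage_seed(config.seed, "nmds"))
        coords = ord_res.to_frame()
        coords.index.name = "sample_id"
        coords.to_csv(out / "nmds.tsv", sep="\t")
        beta_summary = {"nmds": {"stress": ord_res.stress, "k": ord_res.k,
                                 "converged": ord_res.converged,
                                 "n_restarts": ord_res.n_restarts,
                                 "seed": ord_res.seed,
                                 "degenerate": ord_res.degenerate}}
        if len(habitats) >= 2 and metadata.habitat.value_counts().min() >= 2:
            ano = anosim(bc, metadata.habitat.to_dict(),
                         n_permutations=config.n_permutations,
                         seed=_stage_seed(config.seed, "anosim"))
            beta_summary["anosim_habitat"] = {
                "global_r": ano.global_r, "p_value": ano.p_value,
                "n_permutations": ano.n_permutations, "seed": ano.seed}
        _write_json(out / "beta.json", beta_summary)

        stage = "mantel"
        geo = geographic_distance(metadata)
        env = env_distance(metadata)
        env_vars = metadata.env_variables()
        cat_tables = _category_tables(rarefied, assignment)
        mantel_report: dict = {}
        for name, sub in cat_tables.items():
            sub_bc = bray_curtis(sub)
            entry: dict = {"n_otus": sub.n_otus}
            dd = distance_decay(sub_bc, geo,
                                n_permutations=config.n_permutations,
                                seed=_stage_seed(config.seed, f"mantel:{name}:geo"))
            entry["geo_distance"] = dd.mantel.to_dict()
            entry["decay_slope"] = dd.slope
            entry["env_distance"] = mantel(
                sub_bc, env, n_permutations=config.n_permutations,
                seed=_stage_seed(config.seed, f"mantel:{name}:env")).to_dict()
            per_var = {}
            for v in env_vars:
                dv = env_distance(metadata, variables=[v])
                per_var[v] = mantel(
                    sub_bc, dv, n_permutations=config.n_permutations,
                    seed=_stage_seed(config.seed, f"mantel:{name}:{v}")).to_dict()
            entry["per_variable"] = per_var
            mantel_report[name] = entry
        _write_json(out / "mantel.json", mantel_report)

        stage = "varpart"
        basis = pcnm(geo)
        spat = basis.to_frame()
        env_raw = metadata.env_table()
        env_sqrt = env_raw.copy()
        for col in env_sqrt.columns:
            if col != "pH":
                env_sqrt[col] = np.sqrt(env_sqrt[col])
        env_z = (env_sqrt - env_sqrt.mean()) / env_sqrt.std(ddof=1).replace(0.0, 1.0)
        env_f, env_vifrep = vif_filter(env_z)
        spat_f, spat_vifrep = vif_filter(spat)
        n = rarefied.n_samples
        varpart_report: dict = {
            "pcnm": {"n_eigenvectors": int(basis.eigenvectors.shape[1]),
                     "truncation_distance_km": basis.truncation_distance},
            "vif_removed": {"env": env_vifrep.removed, "spatial": spat_vifrep.removed},
        }
        from .beta import hellinger_transform
        for name, sub in cat_tables.items():
            y = hellinger_transform(sub).to_numpy()
            notes: list[str] = []
            if config.forward_selection:
                fs_env = forward_select(y, env_f, alpha=config.alpha,
                                        n_permutations=config.n_permutations,
                                        seed=_stage_seed(config.seed, f"fs_env:{name}"))
                fs_spat = forward_select(y, spat_f, alpha=config.alpha,
                                         n_permutations=config.n_permutations,
                                         seed=_stage_seed(config.seed, f"fs_spat:{name}"))
                env_sel = _predictors_for("env", fs_env.selected, list(env_f.columns), n, notes)
                spat_sel = _predictors_for("spatial", fs_spat.selected, list(spat_f.columns), n, notes)
                selection = {"env": {"selected": fs_env.selected,
                                     "stopping_reason": fs_env.stopping_reason,
                                     "global_adj_r2": fs_env.global_adj_r2,
                                     "global_p": fs_env.global_p},
                             "spatial": {"selected": fs_spat.selected,
                                         "stopping_reason": fs_spat.stopping_reason,
                                         "global_adj_r2": fs_spat.global_adj_r2,
                                         "global_p": fs_spat.global_p}}
            else:
                cap = max(1, n - 3)
                env_sel = list(env_f.columns)[:cap]
                spat_sel = list(spat_f.columns)[:cap]
                selection = {"env": {"selected": env_sel},
                             "spatial": {"selected": spat_sel}}
            total_p = len(env_sel) + len(spat_sel)
            if total_p >= n - 1:
                keep_each = max(1, (n - 2) // 2)
                env_sel = env_sel[:keep_each]
                spat_sel = spat_sel[:keep_each]
                notes.append("predictor sets truncated to keep the model estimable")
            vp = varpart2(y, env_f[env_sel], spat_f[spat_sel],
                          n_permutations=config.n_permutations,
                          seed=_stage_seed(config.seed, f"varpart:{name}"))
            varpart_report[name] = {"selection": selection, "notes": notes,
                                    **vp.to_dict()}
        _write_json(out / "varpart.json", varpart_report)

        stage = "neutral_model"
        ncm_report: dict = {}
        subsets = {"all": rarefied.sample_ids}
        for h in habitats:
            ids = [s for s in rarefied.sample_ids if metadata.habitat[s] == h]
            if len(ids) >= 4:
                subsets[h] = ids
        for name, ids in subsets.items():
            sub = rarefied.select_samples(ids).drop_empty_otus()
            try:
                fit = fit_ncm(occurrence_frequency(sub))
            except ValueError as exc:
                ncm_report[name] = {"error": str(exc)}
                continue
            fit.per_otu.to_csv(out / f"ncm_{name}.tsv", sep="\t", index=False)
            ncm_report[name] = fit.summary()
        _write_json(out / "ncm.json", ncm_report)

        _write_json(out / "manifest.json", manifest)
        return {"manifest": manifest, "classification": classification,
                "beta": beta_summary, "mantel": mantel_report,
                "varpart": varpart_report, "ncm": ncm_report}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def generate_fixtures(scale: str, seed: int, outdir) -> Path:
    """Write a synthetic dataset to ``outdir``.

    ``tiny``: 8 sites x 200 OTUs x 500 reads (CI speed);
    ``paper_like``: 24 sites x ~6000 OTUs x 33996 reads.
    """
    from .simulate import simulate_dataset, simulate_study_layout

    out = Path(outdir)
    rng = np.random.default_rng(seed)
    if scale == "tiny":
        layout = simulate_study_layout(int(rng.integers(2 ** 31)))
        picks = [s for s in layout.sample_ids if s.endswith("1")]  # one per station
        layout = layout.select(picks)
        ds = simulate_dataset(n_species=200, m=0.3, N=550, w=0.3,
                              metadata=layout, seed=int(rng.integers(2 ** 31)))
        # draw down to the nominal 500-read depth so rarefaction is exercised
        ds.table = rarefy(ds.table, 500, int(rng.integers(2 ** 31)))
    elif scale == "paper_like":
        ds = simulate_dataset(n_species=6000, m=0.1, N=33996, w=0.3,
                              seed=int(rng.integers(2 ** 31)))
    else:
        raise ValueError(f"unknown scale {scale!r}")
    ds.write(out)
    return out
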