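"""End-to-end orchestration with deterministic seeding and a manifest.

``run_all`` executes prep → diversity → assembly → traits → quality →
drivers on either a dataset directory or a named synthetic scenario,
writing every stage's tables as TSV plus a JSON run manifest (config
snapshot, per-file SHA-256 hashes, seeds, timestamps, version).

A single global seed is expanded into per-stage seeds through a fixed
counter scheme (SeedSequence spawn keyed by stage index), so toggling
one stage off never shifts another stage's random stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import assembly as assembly_mod
from . import diversity as diversity_mod
from . import drivers as drivers_mod
from . import io as io_mod
from . import quality as quality_mod
from . import simulate as simulate_mod
from . import traits as traits_mod
from .dataset import CommunityDataset

log = logging.getLogger("protcomm")

STAGES = ("prep", "diversity", "assembly", "traits", "quality", "drivers")
# fixed per-stage seed-stream indices (the documented counter scheme)
_STAGE_STREAM = {name: i for i, name in enumerate(("simulate",) + STAGES)}

DEFAULT_CONFIG: dict = {
    "input_dir": None,  # dataset directory; mutually exclusive with scenario
    "scenario": None,  # selection | neutral | greenhouse_vs_openfield
    "n_taxa": 40,
    "per_cell": 6,
    "seed": 0,
    "rarefaction_depth": 18907,
    "exclude_lineages": ["Fungi", "Metazoa", "Embryophyta"],
    "n_null": 999,
    "n_perm": 999,
    "bnti_threshold": 2.0,
    "rc_threshold": 0.95,
    "groupby": "cell",
    "rf_response": "pcoa1",
    "stages": list(STAGES),
}


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict:
    """Read and validate a YAML (plain key: value) run configuration."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError("config must be a mapping of key: value pairs")
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {sorted(unknown)}; valid keys: "
            f"{sorted(DEFAULT_CONFIG)}"
        )
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user)
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: dict) -> None:
    if cfg["rarefaction_depth"] <= 0:
        raise ConfigError("rarefaction_depth must be a positive integer")
    if cfg["n_null"] < 1 or cfg["n_perm"] < 1:
        raise ConfigError("n_null and n_perm must be >= 1")
    bad = set(cfg["stages"]) - set(STAGES)
    if bad:
        raise ConfigError(f"unknown stage(s) {sorted(bad)}; valid: {list(STAGES)}")
    if cfg["input_dir"] is None and cfg["scenario"] is None:
        raise ConfigError("config needs either input_dir or scenario")


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed."""
    child = np.random.SeedSequence(base_seed).spawn(len(_STAGE_STREAM))
    return int(child[_STAGE_STREAM[stage]].generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: str | Path | dict, out_dir: str | Path) -> dict:
    """Run the enabled stages and return the manifest (also written to disk)."""
    cfg = load_config(config) if not isinstance(config, dict) else _merged(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": {k: (sorted(v) if isinstance(v, (set, frozenset)) else v) for k, v in cfg.items()},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    seed = int(cfg["seed"])

    if cfg["input_dir"] is not None:
        dataset = io_mod.load_dataset_dir(cfg["input_dir"])
    else:
        spec = simulate_mod.scenario(
            cfg["scenario"],
            n_taxa=int(cfg["n_taxa"]),
            n_samples_per_cell=int(cfg["per_cell"]),
            seed=stage_seed(seed, "simulate"),
        )
        dataset = simulate_mod.simulate_dataset(spec)

    ordination = None
    for stage in STAGES:
        if stage not in cfg["stages"]:
            log.info("stage %s disabled", stage)
            continue
        t0 = time.time()
        stage_dir = out / stage
        stage_dir.mkdir(exist_ok=True)
        try:
            if stage == "prep":
                dataset = io_mod.prepare(
                    dataset,
                    exclude_lineages=set(cfg["exclude_lineages"]),
                    depth=int(cfg["rarefaction_depth"]),
                    seed=stage_seed(seed, "prep"),
                )
                io_mod.write_community_data(dataset, stage_dir)
            elif stage == "diversity":
                diversity_mod.alpha_table(dataset).to_csv(
                    stage_dir / "alpha.tsv", sep="\t", index_label="sample_id"
                )
                dm = diversity_mod.bray_curtis(dataset)
                pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
                    stage_dir / "bray_curtis.tsv", sep="\t", index_label="sample_id"
                )
                ordination = diversity_mod.pcoa(dm)
                ordination.coordinates.to_csv(
                    stage_dir / "pcoa.tsv", sep="\t", index_label="sample_id"
                )
                rows = []
                for factor in ("mode", "stage"):
                    res = diversity_mod.permanova(
                        dm,
                        dataset.groups(factor),
                        n_perm=int(cfg["n_perm"]),
                        seed=stage_seed(seed, "diversity"),
                    )
                    rows.append(
                        {
                            "factor": factor,
                            "pseudo_F": res.pseudo_F,
                            "R2": res.R2,
                            "p_value": res.p_value,
                            "n_perm": res.n_perm,
                        }
                    )
                pd.DataFrame(rows).to_csv(
                    stage_dir / "permanova.tsv", sep="\t", index=False
                )
            elif stage == "assembly":
                model = assembly_mod.CommunityAssembly(
                    dataset,
                    bnti_threshold=float(cfg["bnti_threshold"]),
                    rc_threshold=float(cfg["rc_threshold"]),
                )
                res = model.fit(
                    n_null=int(cfg["n_null"]),
                    seed=stage_seed(seed, "assembly"),
                    groupby=cfg["groupby"],
                )
                for name, frame in (
                    ("beta_mntd", pd.DataFrame(res.beta_mntd.data,
                                               index=list(res.beta_mntd.ids),
                                               columns=list(res.beta_mntd.ids))),
                    ("beta_nti", res.beta_nti),
                    ("raup_crick", res.raup_crick),
                ):
                    frame.to_csv(stage_dir / f"{name}.tsv", sep="\t",
                                 index_label="sample_id")
                res.classification.to_csv(
                    stage_dir / "classification.tsv", sep="\t", index=False
                )
                res.fractions.to_csv(stage_dir / "fractions.tsv", sep="\t")
            elif stage == "traits":
                assignment = traits_mod.assign_traits(dataset.taxonomy)
                assignment.to_frame().to_csv(
                    stage_dir / "assignment.tsv", sep="\t", index_label="asv_id"
                )
                traits_mod.trait_composition(dataset, assignment).to_csv(
                    stage_dir / "composition.tsv", sep="\t", index_label="sample_id"
                )
            elif stage == "quality":
                if dataset.quality is None:
                    raise ValueError("quality stage needs a quality table")
                pi = quality_mod.production_index(
                    dataset.quality.loc[dataset.sample_ids]
                )
                pi.index.to_frame().to_csv(
                    stage_dir / "production_index.tsv", sep="\t",
                    index_label="sample_id",
                )
                rows = []
                shannon = diversity_mod.alpha_diversity(dataset, "shannon")
                preds = {"shannon": shannon}
                if ordination is not None:
                    preds["pcoa1"] = ordination.coordinates["PC1"]
                for name, pred in preds.items():
                    r = quality_mod.index_regression(pi.index, pred)
                    rows.append(
                        {"predictor": name, "slope": r.slope,
                         "intercept": r.intercept, "R2": r.R2,
                         "p_value": r.p_value}
                    )
                pd.DataFrame(rows).to_csv(
                    stage_dir / "regressions.tsv", sep="\t", index=False
                )
            elif stage == "drivers":
                if dataset.soil is None:
                    raise ValueError("drivers stage needs a soil table")
                rda_res = drivers_mod.RDA(dataset).fit(
                    n_perm=int(cfg["n_perm"]), seed=stage_seed(seed, "drivers")
                )
                rda_res.sample_scores.to_csv(
                    stage_dir / "rda_samples.tsv", sep="\t", index_label="sample_id"
                )
                rda_res.biplot_scores.to_csv(
                    stage_dir / "rda_biplot.tsv", sep="\t", index_label="variable"
                )
                if cfg["rf_response"] == "pcoa1":
                    if ordination is None:
                        ordination = diversity_mod.pcoa(
                            diversity_mod.bray_curtis(dataset)
                        )
                    response = ordination.coordinates["PC1"]
                else:
                    response = dataset.metadata[cfg["rf_response"]]
                ranking = drivers_mod.rf_drivers(
                    dataset.soil.loc[dataset.sample_ids],
                    response,
                    seed=stage_seed(seed, "drivers"),
                )
                frame = ranking.importances.to_frame()
                frame["fit_score_oob_r2"] = ranking.fit_score
                frame.to_csv(stage_dir / "rf_importance.tsv", sep="\t",
                             index_label="variable")
        except Exception as exc:
            log.error("stage %s failed: %s", stage, exc)
            raise RuntimeError(f"pipeline aborted at stage {stage!r}: {exc}") from exc
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "seed": stage_seed(seed, stage),
            "outputs": {
                p.name: _sha256(p) for p in sorted(stage_dir.glob("*")) if p.is_file()
            },
        }
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _merged(user: dict) -> dict:
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {sorted(unknown)}; valid keys: "
            f"{sorted(DEFAULT_CONFIG)}"
        )
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user)
    _validate_config(cfg)
    return cfg
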