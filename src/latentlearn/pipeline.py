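"""End-to-end orchestration of the analysis stages.

Stages run in dependency order: synth (or ingest) -> behavior -> fit_beta
-> rsa -> geometry -> dynamics.  Each stage reads its inputs from, and
writes its outputs to, a single run directory; a manifest records the
configuration, seeds, parameters and output checksums so that a re-run
with an identical configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import dynamics as dyn
from . import maxent, rsa
from .geometry import classical_mds, lda_module_loss
from .graphs import GraphSpec, transition_matrix
from .synthetic import SynthConfig, gen_behavior, gen_neural

__all__ = ["RunConfig", "run_pipeline", "DependencyError", "ConfigError"]

logger = logging.getLogger("latentlearn.pipeline")

STAGES = ("synth", "behavior", "fit_beta", "rsa", "geometry", "dynamics")


class ConfigError(ValueError):
    """Invalid run configuration."""


class DependencyError(RuntimeError):
    """An enabled stage is missing the output of an upstream stage."""


@dataclasses.dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    synth: dict = dataclasses.field(default_factory=dict)
    alignment: str = "stimulus"
    n_perm: int = 100
    structured_channels: tuple[int, ...] = (2, 5, 9)
    window_width: int = 500
    window_step: int = 100

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        try:
            payload = json.loads(Path(path).read_text())
            return cls(**payload)
        except (TypeError, json.JSONDecodeError) as exc:
            raise ConfigError(str(exc)) from exc

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(s for s in STAGES if s in self.stages)
        if self.alignment not in ("stimulus", "middle", "response"):
            raise ConfigError("alignment must be stimulus, middle, or response")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage '{needed_by}' needs {path.name}; run stage '{stage}' first"
        )
    return path


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages and return the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO)
    manifest: dict = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "stages_run": [],
        "outputs": {},
    }

    synth_cfg = SynthConfig(seed=cfg.seed, **cfg.synth)

    if "synth" in cfg.stages:
        logger.info("stage synth")
        g = synth_cfg.graph()
        x, table = gen_behavior(synth_cfg)
        (out / "graph.json").write_text(g.to_json())
        pd.DataFrame({"node": x}).to_csv(out / "walk.csv", index=False)
        table.drop(columns=["a_true"]).to_csv(out / "trials.csv", index=False)
        A = transition_matrix(g)
        template = rsa.latent_template(maxent.analytic_estimate(A, synth_cfg.beta_true))
        epochs = gen_neural(synth_cfg, template, cfg.structured_channels)
        epochs.to_hdf5(out / "epochs.h5")
        manifest["stages_run"].append("synth")

    if "behavior" in cfg.stages:
        logger.info("stage behavior")
        trials = pd.read_csv(_require(out / "trials.csv", "synth", "behavior"))
        walk = pd.read_csv(_require(out / "walk.csv", "synth", "behavior"))["node"].to_numpy()
        filtered = bhv.filter_trials(bhv.attach_covariates(trials, walk))
        resid = bhv.residualize_rt(filtered)
        resid.to_csv(out / "resid.csv", index=False)
        manifest["stages_run"].append("behavior")

    if "fit_beta" in cfg.stages:
        logger.info("stage fit_beta")
        walk = pd.read_csv(_require(out / "walk.csv", "synth", "fit_beta"))["node"].to_numpy()
        resid = pd.read_csv(_require(out / "resid.csv", "behavior", "fit_beta"))
        g = GraphSpec.from_json(_require(out / "graph.json", "synth", "fit_beta").read_text())
        model = maxent.TemporalDiscountingModel(
            walk, resid, n_nodes=g.n_nodes, transition_matrix=transition_matrix(g)
        )
        fit = model.fit()
        (out / "fit.json").write_text(json.dumps(fit.to_dict(), sort_keys=True, indent=2))
        logger.info("fitted beta=%s status=%s", fit.beta, fit.status)
        manifest["stages_run"].append("fit_beta")

    if "rsa" in cfg.stages:
        logger.info("stage rsa")
        epochs = rsa.EpochArray.from_hdf5(_require(out / "epochs.h5", "synth", "rsa"))
        fit = json.loads(_require(out / "fit.json", "fit_beta", "rsa").read_text())
        g = GraphSpec.from_json(_require(out / "graph.json", "synth", "rsa").read_text())
        A = transition_matrix(g)
        beta = fit["beta"] if fit["beta"] is not None else 1.0
        latent = rsa.latent_template(maxent.analytic_estimate(A, max(beta, 1e-3)))
        exact = rsa.latent_template(A)
        visual = rsa.visual_template(n_nodes=g.n_nodes)
        truncated = rsa.truncate_epochs(epochs, cfg.alignment)
        sel = rsa.contact_selection(
            truncated, latent, exact, visual=visual, n_perm=cfg.n_perm, seed=cfg.seed + 1
        )
        payload = {k: np.asarray(v).tolist() for k, v in sel.items()}
        (out / "selection.json").write_text(json.dumps(payload, sort_keys=True, indent=2))
        manifest["stages_run"].append("rsa")

    if "geometry" in cfg.stages:
        logger.info("stage geometry")
        epochs = rsa.EpochArray.from_hdf5(_require(out / "epochs.h5", "synth", "geometry"))
        sel = json.loads(_require(out / "selection.json", "rsa", "geometry").read_text())
        g = GraphSpec.from_json(_require(out / "graph.json", "synth", "geometry").read_text())
        selected = [i for i, s in enumerate(sel["selected_latent"]) if s]
        result: dict = {"selected_channels": selected}
        if selected:
            truncated = rsa.truncate_epochs(epochs, cfg.alignment)
            combined = rsa.cv_euclidean_rdm(
                rsa.EpochArray(
                    data=truncated.data[selected],
                    fs=truncated.fs,
                    labels=truncated.labels,
                    rts=truncated.rts,
                    alignment=truncated.alignment,
                    n_nodes=truncated.n_nodes,
                )
            )
            pd.DataFrame(combined.values).to_csv(out / "rdm_selected.csv", index=False)
            emb = classical_mds(combined)
            pd.DataFrame(
                {"node": np.arange(g.n_nodes), "x": emb.coords[:, 0], "y": emb.coords[:, 1]}
            ).to_csv(out / "embedding.csv", index=False)
            if g.module_labels is not None:
                result["module_loss"] = lda_module_loss(emb, g.module_labels)
        (out / "geometry.json").write_text(json.dumps(result, sort_keys=True, indent=2))
        manifest["stages_run"].append("geometry")

    if "dynamics" in cfg.stages:
        logger.info("stage dynamics")
        epochs = rsa.EpochArray.from_hdf5(_require(out / "epochs.h5", "synth", "dynamics"))
        sel = json.loads(_require(out / "selection.json", "rsa", "dynamics").read_text())
        fit = json.loads(_require(out / "fit.json", "fit_beta", "dynamics").read_text())
        walk = pd.read_csv(_require(out / "walk.csv", "synth", "dynamics"))["node"].to_numpy()
        resid = pd.read_csv(_require(out / "resid.csv", "behavior", "dynamics"))
        g = GraphSpec.from_json(_require(out / "graph.json", "synth", "dynamics").read_text())
        A = transition_matrix(g)
        beta = fit["beta"] if fit["beta"] is not None else 1.0
        latent = rsa.latent_template(maxent.analytic_estimate(A, max(beta, 1e-3)))
        visual = rsa.visual_template(n_nodes=g.n_nodes)
        truncated = rsa.truncate_epochs(epochs, cfg.alignment)
        w = dyn.sliding_windows(len(walk), cfg.window_width, cfg.window_step)
        selected = [i for i, s in enumerate(sel["selected_latent"]) if s]
        if selected:
            table = dyn.windowed_template_corr(
                truncated, {"latent": latent, "visual": visual}, w, channels=selected
            )
            table.to_csv(out / "dynamics_windows.csv", index=False)
        wb = dyn.windowed_beta(walk, resid, w, n_nodes=g.n_nodes)
        wb.to_csv(out / "dynamics_beta.csv", index=False)
        manifest["stages_run"].append("dynamics")

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2))
    return manifest
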