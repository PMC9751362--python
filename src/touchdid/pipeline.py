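"""End-to-end orchestration: simulate -> filter -> proportion -> panel ->
DID / event study -> quality, with a reproducibility manifest.

Every stage writes its output in an open format (JSONL / CSV / JSON) so
any stage can be re-run from intermediates or swapped for a real-data
front end; the manifest records per-stage seeds and output hashes so a
re-run from the same seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .config import ATTITUDES, SimulationConfig
from .did import DIDEstimator, EventStudyEstimator, subset_dataset
from .errors import ConfigurationError
from .filtering import FilterReport, classify_targets, dedupe_exact, drop_url_records
from .lexicon import TargetLexicon, default_lexicon
from .panel import assemble_panel, build_groups
from .proportion import stream_monthly_samples, _residue
from .quality import bootstrap_delta, similarity_panel, top_bottom
from .simulate import generate_stream, write_stream

log = logging.getLogger("touchdid")


class PipelineConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    outdir: str = "touchdid-out"
    seed: Optional[int] = None  # overrides simulation.seed when set
    lexicon_path: Optional[str] = None
    models: tuple[str, ...] = ("overall", "waves")
    bootstrap_B: int = 10_000
    bootstrap_alpha: float = 0.05
    bootstrap_n_tested: int = 30
    top_bottom_k: int = 15
    save_stream: bool = True
    zero_policy: str = "shift"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _word_cells(classified: pd.DataFrame) -> pd.DataFrame:
    """(calendar_month, sample_index, attitude, word, count) from records."""
    df = classified.copy()
    df["calendar_month"] = df["timestamp"].dt.to_period("M").astype(str)
    df["date"] = df["timestamp"].dt.normalize()
    df["sample_index"] = _residue(df["date"])
    return (
        df.groupby(["calendar_month", "sample_index", "attitude", "target_word"], observed=True)
        .size().rename("count").reset_index()
        .rename(columns={"target_word": "word"})
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write outputs under ``config.outdir`` and return the
    manifest.  Stage failures abort with the failing stage named."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    if config.seed is not None:
        sim = sim.model_copy(update={"seed": config.seed})
    groups = build_groups()
    needed = pd.PeriodIndex(sorted({m for g in groups for m in g.months}), freq="M")
    span = sim.months
    if needed.min() < span.min() or needed.max() > span.max():
        raise ConfigurationError(
            f"simulation {span.min()}..{span.max()} does not cover the panel "
            f"window {needed.min()}..{needed.max()}"
        )
    lexicon = (
        TargetLexicon.from_csv(config.lexicon_path)
        if config.lexicon_path
        else default_lexicon()
    )
    seed_seq = np.random.SeedSequence(sim.seed)
    stage_seeds = {
        name: int(ss.generate_state(1)[0])
        for name, ss in zip(("proportion", "quality"), seed_seq.spawn(2))
    }
    manifest: dict = {
        "version": __version__,
        "seed": sim.seed,
        "stage_seeds": stage_seeds,
        "config": json.loads(config.model_copy(update={"simulation": sim}).model_dump_json()),
        "outputs": {},
    }

    def _emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": path.name, "sha256": _sha256(path)}

    stage = "simulate"
    try:
        log.info("stage %s", stage)
        stream = generate_stream(sim, lexicon)
        if config.save_stream:
            p = outdir / "stream.jsonl"
            write_stream(stream, p)
            _emit("stream", p)
        sim.to_yaml(outdir / "simulation.yaml")
        _emit("simulation_config", outdir / "simulation.yaml")

        stage = "filter"
        log.info("stage %s", stage)
        report = FilterReport(collected=len(stream))
        deduped, _ = dedupe_exact(stream)
        report.after_dedup = len(deduped)
        clean, _ = drop_url_records(deduped)
        report.after_url_drop = len(clean)
        att = clean[clean["attitude"].isin(("desire", "avoidance"))]
        with_target = att[att["target_word"].notna()]
        report.with_target = len(with_target)
        classified = classify_targets(clean, lexicon)
        report.after_blocklist = len(classified)
        report.assert_monotone()
        p = outdir / "filter_report.json"
        p.write_text(json.dumps(report.to_dict(), indent=2))
        _emit("filter_report", p)

        stage = "proportion"
        log.info("stage %s", stage)
        samples = stream_monthly_samples(clean, lexicon, needed,
                                         seed=stage_seeds["proportion"])
        p = outdir / "monthly_samples.csv"
        samples.to_csv(p, index=False)
        _emit("monthly_samples", p)

        stage = "panel"
        log.info("stage %s", stage)
        panel = assemble_panel(samples, groups)
        p = outdir / "panel.csv"
        panel.to_csv(p, index=False)
        _emit("panel", p)

        stage = "did"
        log.info("stage %s", stage)
        did_rows = []
        for attitude in ATTITUDES:
            for animacy in ("animate", "inanimate"):
                data = subset_dataset(panel, attitude, animacy)
                for model in config.models:
                    est = DIDEstimator(model=model, zero_policy=config.zero_policy).fit(data)
                    did_rows.append(
                        est.effects_.assign(model=model, attitude=attitude,
                                            animacy=animacy, response="proportion")
                    )
        did_table = pd.concat(did_rows, ignore_index=True)
        p = outdir / "did_effects.csv"
        did_table.to_csv(p, index=False)
        _emit("did_effects", p)

        stage = "event-study"
        log.info("stage %s", stage)
        es_rows = []
        for attitude in ATTITUDES:
            for animacy in ("animate", "inanimate"):
                data = subset_dataset(panel, attitude, animacy)
                est = EventStudyEstimator(zero_policy=config.zero_policy).fit(data)
                es_rows.append(est.curve_.assign(attitude=attitude, animacy=animacy))
        es_table = pd.concat(es_rows, ignore_index=True)
        p = outdir / "event_study.csv"
        es_table.to_csv(p, index=False)
        _emit("event_study", p)

        stage = "quality"
        log.info("stage %s", stage)
        words = _word_cells(classified)
        sim_rows, delta_frames, tb = [], [], {}
        treat = next(g for g in groups if g.treat)
        post_months = treat.months[6:].astype(str)
        for attitude in ATTITUDES:
            spanel = similarity_panel(words, attitude=attitude)
            for model in config.models:
                est = DIDEstimator(model=model, zero_policy=config.zero_policy).fit(spanel)
                sim_rows.append(est.effects_.assign(model=model, attitude=attitude,
                                                    response="similarity"))
            wa = words[words["attitude"] == attitude]
            t_counts = wa[wa["calendar_month"].isin(post_months)].groupby("word")["count"].sum()
            ctrl_months = {
                m for g in groups if not g.treat for m in g.months[6:].astype(str)
            }
            c_counts = wa[wa["calendar_month"].isin(ctrl_months)].groupby("word")["count"].sum()
            deltas = bootstrap_delta(
                t_counts, c_counts, B=config.bootstrap_B,
                alpha=config.bootstrap_alpha, n_tested=config.bootstrap_n_tested,
                seed=stage_seeds["quality"],
            )
            delta_frames.append(deltas.assign(attitude=attitude))
            sel = top_bottom(deltas, k=config.top_bottom_k)
            tb[attitude] = sel.to_dict(orient="records")
        p = outdir / "similarity_did.csv"
        pd.concat(sim_rows, ignore_index=True).to_csv(p, index=False)
        _emit("similarity_did", p)
        p = outdir / "target_deltas.csv"
        pd.concat(delta_frames, ignore_index=True).to_csv(p, index=False)
        _emit("target_deltas", p)
        p = outdir / "top_bottom.json"
        p.write_text(json.dumps(tb, indent=2, default=float))
        _emit("top_bottom", p)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
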