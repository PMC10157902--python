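"""Pre/post paired statistics, Bonferroni correction, group contrast tables,
and the end-to-end synthetic-cohort pipeline."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _st

from .bci import assign_performance_group, chance_threshold, score_subject
from .connectivity import global_plv
from .io import (
    ALPHA,
    BandDefinition,
    RawRecording,
    extract_epochs,
    filter_signal,
    reject_epochs,
)
from .spectral import prestimulus_power
from .synthetic import PostEffect, SyntheticConfig, generate_subject

__all__ = [
    "TTestResult",
    "paired_t_test",
    "bonferroni",
    "compare_pre_post",
    "run_pipeline",
]


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False  # zero-variance differences with nonzero mean

    def __iter__(self):
        return iter((self.t, self.df, self.p))


def paired_t_test(pre, post) -> TTestResult:
    """Two-sided paired Student's t-test on d = post - pre."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D vectors of equal length")
    n = len(pre)
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = post - pre
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.allclose(d, 0.0):
            return TTestResult(t=0.0, df=n - 1, p=1.0)
        # all differences identical and nonzero: t diverges
        return TTestResult(t=np.inf * np.sign(d[0]), df=n - 1,
                           p=np.finfo(float).tiny, degenerate=True)
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * _st.t.sf(abs(t), df=n - 1))
    return TTestResult(t=t, df=n - 1, p=p)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Elementwise p_adj = min(1, m * p); m defaults to the count."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m is None else m
    return np.minimum(1.0, m * p)


def compare_pre_post(measures: pd.DataFrame, correct_channels: bool = True) -> pd.DataFrame:
    """Group contrast table from per-subject pre/post measures.

    ``measures`` columns: subject, arm, group, measure, pre, post and an
    optional ``channel`` column.  One output row per (arm, group, measure
    [, channel]); rows carrying a channel get Bonferroni over the channels of
    their (arm, group, measure) family.
    """
    required = {"subject", "arm", "group", "measure", "pre", "post"}
    missing = required - set(measures.columns)
    if missing:
        raise ValueError(f"measures table missing columns {sorted(missing)}")
    df = measures.copy()
    if "channel" not in df.columns:
        df["channel"] = None
    if df[["pre", "post"]].isna().any().any():
        raise ValueError("every subject needs both a pre and a post value")
    rows = []
    for (arm, group, measure), g in df.groupby(["arm", "group", "measure"], sort=True):
        for channel, gc in g.groupby("channel", dropna=False, sort=True):
            if len(gc) < 2:
                raise ValueError(
                    f"group ({arm}, {group}, {measure}) has a single subject (df = 0)"
                )
            res = paired_t_test(gc["pre"].to_numpy(), gc["post"].to_numpy())
            rows.append(
                dict(
                    arm=arm, group=group, measure=measure,
                    channel=None if pd.isna(channel) else channel,
                    pre_mean=float(gc["pre"].mean()),
                    post_mean=float(gc["post"].mean()),
                    delta=float(gc["post"].mean() - gc["pre"].mean()),
                    t=res.t, df=res.df, p=res.p,
                    n_subjects=len(gc),
                )
            )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = out["p"]
    if correct_channels:
        with_ch = out["channel"].notna()
        for _, idx in out[with_ch].groupby(["arm", "group", "measure"]).groups.items():
            out.loc[idx, "p_adjusted"] = bonferroni(out.loc[idx, "p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# End-to-end synthetic-cohort pipeline
# ---------------------------------------------------------------------------

_BP_1_40 = BandDefinition("bp", 1.0, 40.0)

DEFAULT_PIPELINE_CONFIG = {
    "seed": 1,
    "arms": {
        "sham": {"n_subjects": 6, "post_effect": {}},
        "vibrotactile": {
            "n_subjects": 6,
            "post_effect": {"erd_depth": 0.25, "prestim_alpha_amp": 4.0, "coupling": 0.2},
        },
        "tdcs": {
            "n_subjects": 6,
            "post_effect": {"erd_depth": 0.15, "prestim_alpha_amp": 2.0, "coupling": 0.1},
        },
    },
    "subject": {"n_trials_per_block": 10, "erd_depth_range": [0.05, 0.7]},
    "measures": ["accuracy", "bandpower", "global_plv"],
}


def _prestim_alpha_db(raw, events, session):
    x = filter_signal(raw.samples, raw.fs, "bandpass", _BP_1_40)
    filtered = RawRecording(x, raw.fs, raw.channel_labels, dict(raw.meta))
    epochs = extract_epochs(filtered, events, (-1000.0, 4000.0),
                            session=session, phase="online")
    kept, _ = reject_epochs(epochs)
    return prestimulus_power(kept, ALPHA).c3c4_mean


def _global_plv_alpha(raw, events, session):
    epochs = extract_epochs(raw, events, (-1000.0, 4000.0),
                            session=session, phase="online")
    kept, _ = reject_epochs(epochs)
    out = {}
    for label in ("left", "right"):
        out[label] = global_plv(kept, ALPHA, label, session=session).global_value
    return out


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """simulate -> preprocess -> score -> bandpower -> plv -> stats.

    Deterministic under the config seed.  Returns the report bundle; when
    ``out_dir`` is given also writes ``report.json`` and ``report.md``.
    """
    cfg = {**DEFAULT_PIPELINE_CONFIG, **(config or {})}
    if not cfg["arms"] or all(a.get("n_subjects", 0) == 0 for a in cfg["arms"].values()):
        raise ValueError("pipeline config lists zero subjects")
    master_seed = int(cfg["seed"])
    subject_cfg = dict(cfg.get("subject", {}))
    erd_range = subject_cfg.pop("erd_depth_range", [0.05, 0.7])
    measures_on = set(cfg.get("measures", ["accuracy"]))
    threshold = chance_threshold(80)

    subject_rows = []
    measure_rows = []
    for arm_i, (arm, arm_cfg) in enumerate(sorted(cfg["arms"].items())):
        post_effect = PostEffect(**arm_cfg.get("post_effect", {}))
        for s in range(int(arm_cfg["n_subjects"])):
            seed = master_seed * 100000 + arm_i * 1000 + s
            rng = np.random.default_rng(seed)
            erd = float(rng.uniform(*erd_range))
            scfg = SyntheticConfig(seed=seed, erd_depth=erd,
                                   post_effect=post_effect, **subject_cfg)
            try:
                raw, events, truth = generate_subject(scfg)
                sid = raw.meta["subject"]
                recs = {ses: score_subject(raw, events, ses, subject=sid)
                        for ses in ("pre", "post")}
            except Exception as exc:  # pragma: no cover - stage diagnostics
                raise RuntimeError(f"[simulate/score] subject seed {seed} failed: {exc}") from exc
            if any(r.meta.get("quality") == "exclude" for r in recs.values()):
                continue
            group = assign_performance_group(recs["pre"], threshold)
            subject_rows.append(
                dict(subject=sid, arm=arm, group=group, erd_depth=erd,
                     pre_accuracy=recs["pre"].accuracy, post_accuracy=recs["post"].accuracy)
            )
            if "accuracy" in measures_on:
                measure_rows.append(dict(subject=sid, arm=arm, group=group,
                                         measure="accuracy",
                                         pre=recs["pre"].accuracy,
                                         post=recs["post"].accuracy))
            if "bandpower" in measures_on:
                try:
                    pre_db = _prestim_alpha_db(raw, events, "pre")
                    post_db = _prestim_alpha_db(raw, events, "post")
                except Exception as exc:  # pragma: no cover
                    raise RuntimeError(f"[bandpower] subject seed {seed} failed: {exc}") from exc
                measure_rows.append(dict(subject=sid, arm=arm, group=group,
                                         measure="prestim_alpha_c3c4_db",
                                         pre=pre_db, post=post_db))
            if "global_plv" in measures_on:
                try:
                    pre_plv = _global_plv_alpha(raw, events, "pre")
                    post_plv = _global_plv_alpha(raw, events, "post")
                except Exception as exc:  # pragma: no cover
                    raise RuntimeError(f"[plv] subject seed {seed} failed: {exc}") from exc
                for label in ("left", "right"):
                    measure_rows.append(dict(subject=sid, arm=arm, group=group,
                                             measure=f"global_plv_alpha_{label}",
                                             pre=pre_plv[label], post=post_plv[label]))

    measures_df = pd.DataFrame(measure_rows)
    # drop single-subject (arm, group) cells: a paired test has no df there
    dropped = []
    if len(measures_df):
        sizes = measures_df.groupby(["arm", "group", "measure"])["subject"].transform("size")
        dropped = measures_df[sizes < 2][["arm", "group", "measure"]].drop_duplicates()
        dropped = dropped.to_dict("records")
        measures_df = measures_df[sizes >= 2]
    contrasts = compare_pre_post(measures_df) if len(measures_df) else pd.DataFrame()

    report = {
        "config": cfg,
        "chance_threshold_pct": threshold,
        "subjects": subject_rows,
        "contrasts": contrasts.to_dict("records"),
        "dropped_single_subject_cells": dropped,
        "table": _format_table(subject_rows),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        (out / "report.md").write_text(_markdown_report(report))
    return report


def _fmt_range(values) -> str:
    v = np.asarray(values, dtype=float)
    return f"{v.mean():.2f} ({v.min():g} ~ {v.max():g}%)"


def _format_table(subject_rows) -> dict:
    """Per arm x group 'mean (min ~ max)' accuracy strings, pre and post."""
    df = pd.DataFrame(subject_rows)
    table = {}
    if not len(df):
        return table
    for (arm, group), g in df.groupby(["arm", "group"]):
        table[f"{arm}/{group}"] = {
            "pre": _fmt_range(g["pre_accuracy"]),
            "post": _fmt_range(g["post_accuracy"]),
            "n": len(g),
        }
    return table


def _markdown_report(report: dict) -> str:
    lines = ["# Synthetic cohort report", ""]
    lines.append(f"Chance threshold: {report['chance_threshold_pct']:.2f}%")
    lines.append("")
    lines.append("## BCI performance (%)")
    lines.append("")
    lines.append("| arm/group | n | pre | post |")
    lines.append("|---|---|---|---|")
    for key, row in sorted(report["table"].items()):
        lines.append(f"| {key} | {row['n']} | {row['pre']} | {row['post']} |")
    lines.append("")
    lines.append("## Pre/post contrasts")
    lines.append("")
    lines.append("| arm | group | measure | pre | post | delta | t | p | p_adj | n |")
    lines.append("|---|---|---|---|---|---|---|---|---|---|")
    for r in report["contrasts"]:
        lines.append(
            f"| {r['arm']} | {r['group']} | {r['measure']} | {r['pre_mean']:.3f} "
            f"| {r['post_mean']:.3f} | {r['delta']:+.3f} | {r['t']:.3f} "
            f"| {r['p']:.4f} | {r['p_adjusted']:.4f} | {r['n_subjects']} |"
        )
    lines.append("")
    return "\n".join(lines)
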