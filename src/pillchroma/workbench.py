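"""End-to-end experiment orchestration at desk scale.

One call reproduces the whole study design: render the 19-pill catalog
under the reference condition and the 12 real-world conditions, segment
every frame, measure per-pill ΔE against the reference, train the
surrogate recognizer on reference images, evaluate top-1/top-5 accuracy
per condition, and run the repeated-measures analyses — emitting tidy
CSV/JSON outputs, a provenance log and a two-panel figure mirroring the
study's accuracy and colour-difference comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import build_catalog, condition_grid, reference_condition
from .color import (WHITEPOINTS, WhitePoint, condition_delta_e, roi_mean_color)
from .recognize import evaluate_topk, featurize, fit_classifier
from .render import RenderParams, generate_records
from .roi import (BoundingBox, RoiConfig, RoiResult, SegmentationError,
                  extract_roi)
from .stats import (accuracy_vs_delta_e, delta_e_table, ev_stratified_anova,
                    summarize_delta_e, three_way_rm_anova)

_FLOAT_FMT = "%.6f"


@dataclass
class ExperimentConfig:
    """Everything a run needs; serialisable to/from YAML."""

    seed: int = 0
    n_per_cell: int = 2
    canvas_size: tuple[int, int] = (128, 128)
    render: RenderParams = field(default_factory=RenderParams)
    roi: RoiConfig = field(default_factory=RoiConfig)
    ks: tuple[int, ...] = (1, 5)
    whitepoint: str = "anchored"
    gg_correction: bool = False
    out_dir: str = "scratch/experiment"

    def validate(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError(f"n_per_cell must be ≥ 1, got {self.n_per_cell}")
        if min(self.canvas_size) < 64:
            raise ValueError("canvas_size must be at least 64×64")
        if self.whitepoint not in WHITEPOINTS:
            raise ValueError(f"unknown whitepoint {self.whitepoint!r}")
        if any(k < 1 for k in self.ks):
            raise ValueError("every k must be ≥ 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "render" in raw:
            raw["render"] = RenderParams(**raw["render"])
        if "roi" in raw:
            raw["roi"] = RoiConfig(**raw["roi"])
        for key in ("canvas_size", "ks"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["canvas_size"] = list(self.canvas_size)
        d["ks"] = list(self.ks)
        return d


@dataclass
class ExperimentBundle:
    """All tables a run produces; the reporter adds no numbers to these."""

    condition_table: pd.DataFrame     # condition, top1, top5, mean/sd ΔE
    delta_e_records: pd.DataFrame     # per (pill, condition) ΔE
    anova_three_way: pd.DataFrame
    anova_stratified: pd.DataFrame
    pairwise: pd.DataFrame
    association: dict
    segmentation_log: pd.DataFrame    # per-condition fallback/failure counts
    provenance: dict


def _segment_record(rec, roi_config: RoiConfig):
    """Segment one frame; on total failure fall back to the full frame
    so the factorial ΔE design stays complete (failure is logged)."""
    try:
        res = extract_roi(rec.image, roi_config)
        return res, res.strategy, False
    except SegmentationError:
        h, w = rec.image.shape[:2]
        full = np.ones((h, w), dtype=bool)
        res = RoiResult(roi=rec.image.copy(), mask=full, roi_mask=full,
                        bbox=BoundingBox(0, 0, h, w), strategy="full-frame",
                        fallback_used=True)
        return res, "full-frame", True


def run_experiment(config: ExperimentConfig) -> ExperimentBundle:
    """Execute generate → segment → colordiff → classify → analyze."""
    config.validate()
    white: WhitePoint = WHITEPOINTS[config.whitepoint]()
    catalog = build_catalog(config.seed)
    reference = reference_condition()
    grid = condition_grid()

    records = generate_records(catalog, [reference, *grid], config.n_per_cell,
                               config.seed, config.canvas_size, config.render)

    seg_counts: dict[str, dict[str, int]] = {}
    ref_colors, cond_colors = [], []
    train, test = [], []
    for rec in records:
        res, strategy, failed = _segment_record(rec, config.roi)
        log = seg_counts.setdefault(rec.condition, {"n": 0, "contour": 0,
                                                    "threshold": 0, "full-frame": 0})
        log["n"] += 1
        log[strategy] += 1
        mean_rgb = roi_mean_color(res.roi, res.roi_mask)
        fv = featurize(res.roi, res.roi_mask, white) if not failed else None
        if rec.condition == reference.name:
            ref_colors.append((rec.label, mean_rgb))
            if fv is not None:
                train.append((fv, rec.label))
        else:
            cond_colors.append((rec.label, rec.condition, mean_rgb))
            test.append((fv, rec.label, rec.condition))

    de_records = condition_delta_e(ref_colors, cond_colors, white)
    de_df = delta_e_table(de_records)
    summary = summarize_delta_e(de_records)

    model = fit_classifier(train, expected_labels=[p.label for p in catalog])
    topk = evaluate_topk(model, test, ks=config.ks)
    acc_df = pd.DataFrame([{"condition": r.condition_name, "k": r.k,
                            "accuracy": r.accuracy, "n": r.n_eval}
                           for r in topk])

    anova3 = pd.DataFrame([asdict(r) for r in
                           three_way_rm_anova(de_df, config.gg_correction)])
    strat, pairs = ev_stratified_anova(de_df)
    strat_df = pd.DataFrame([asdict(r) for r in strat])
    pair_df = pd.DataFrame([
        {"background": p.stratum[0], "flash": p.stratum[1],
         "ev_a": p.pair[0], "ev_b": p.pair[1],
         "raw_p": p.raw_p, "adjusted_p": p.adjusted_p} for p in pairs])
    association = accuracy_vs_delta_e(topk, summary)

    acc_wide = acc_df.pivot(index="condition", columns="k", values="accuracy")
    cond_table = summary.merge(
        acc_wide.rename(columns={k: f"top{k}" for k in config.ks}),
        on="condition")
    order = [c.name for c in grid]
    cond_table = (cond_table.set_index("condition").loc[order].reset_index())

    seg_df = pd.DataFrame([
        {"condition": cond, **counts} for cond, counts in seg_counts.items()])

    provenance = {
        "package": "pillchroma", "version": __version__,
        "config": config.to_dict(),
        "n_images": len(records), "n_conditions": len(grid),
        "n_pills": len(catalog),
    }
    return ExperimentBundle(
        condition_table=cond_table, delta_e_records=de_df,
        anova_three_way=anova3, anova_stratified=strat_df, pairwise=pair_df,
        association=association, segmentation_log=seg_df, provenance=provenance)


def write_bundle(bundle: ExperimentBundle, out_dir: str | Path) -> Path:
    """Write every table of the bundle as CSV/JSON under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in (("condition_table", bundle.condition_table),
                     ("delta_e_records", bundle.delta_e_records),
                     ("anova_three_way", bundle.anova_three_way),
                     ("anova_stratified", bundle.anova_stratified),
                     ("pairwise_comparisons", bundle.pairwise),
                     ("segmentation_log", bundle.segmentation_log)):
        df.to_csv(out / f"{name}.csv", index=False, float_format=_FLOAT_FMT,
                  lineterminator="\n")
    with open(out / "association.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.association, fh, indent=1, sort_keys=True)
    with open(out / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.provenance, fh, indent=1, sort_keys=True)
    return out


def write_report(bundle: ExperimentBundle, out_dir: str | Path) -> Path:
    """Two-panel figure (top-k accuracy; ΔE mean±SD per condition) and a
    markdown summary. Purely presentational: every number comes from the
    bundle's tables."""
    for name in ("condition_table", "anova_three_way"):
        df = getattr(bundle, name)
        if df is None or len(df) == 0:
            raise ValueError(f"bundle component {name} is missing or empty")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tab = bundle.condition_table
    conds = tab["condition"].tolist()
    x = np.arange(len(conds))

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(10, 7), sharex=True)
    width = 0.38
    acc_cols = [c for c in tab.columns if c.startswith("top")]
    for i, col in enumerate(acc_cols):
        ax1.bar(x + (i - (len(acc_cols) - 1) / 2) * width, tab[col] * 100,
                width, label=col)
    ax1.set_ylabel("accuracy (%)")
    ax1.set_ylim(0, 105)
    ax1.legend()
    ax1.set_title("A: top-k recognition accuracy per condition")

    ax2.bar(x, tab["mean_delta_e"], 0.6, yerr=tab["sd_delta_e"], capsize=3,
            color="#888888")
    ax2.set_ylabel("ΔE (mean ± SD)")
    ax2.set_title("B: colour difference vs reference per condition")
    ax2.set_xticks(x)
    ax2.set_xticklabels(conds, rotation=45, ha="right")
    fig.tight_layout()
    fig.savefig(out / "report.png", dpi=120)
    plt.close(fig)

    lines = ["# Condition report", "",
             "| condition | " + " | ".join(acc_cols) + " | mean ΔE | sd ΔE | n |",
             "|---|" + "---|" * (len(acc_cols) + 3)]
    for _, row in tab.iterrows():
        accs = " | ".join(f"{row[c]:.3f}" for c in acc_cols)
        lines.append(f"| {row['condition']} | {accs} | "
                     f"{row['mean_delta_e']:.3f} | {row['sd_delta_e']:.3f} | "
                     f"{int(row['n'])} |")
    lines += ["", "## Accuracy vs ΔE (Spearman)", ""]
    for k, rho in sorted(bundle.association["spearman"].items()):
        lines.append(f"- top-{k}: rho = {rho:.3f}")
    (out / "report.md").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return out
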