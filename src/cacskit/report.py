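"""End-to-end run orchestration and human-readable report assembly.

A run generates a seeded phantom cohort, splits it 80/20 by case, trains the
multiview model on the training split, scores every test case twice — once
from the model-predicted mask (automatic arm) and once from the ground-truth
mask (manual arm) — and runs the full agreement battery between the two
arms. All randomness flows from a single root seed expanded per stage; the
JSON artifacts are a pure function of the run config, with wall-clock
timestamps confined to the run log.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import agreement
from .core_io import CtVolume, VesselLabelMask
from .mvsc import MvscConfig, predict_mask, predict_scores, train
from .phantom import standard_cohort, write_cohort
from .scoring import CacsResult, ScoringConfig, score_case


@dataclass
class RunConfig:
    """Everything that determines an end-to-end run's outputs."""

    seed: int = 0
    n_cases: int = 10
    shape: tuple[int, int, int] = (24, 96, 96)
    spacing: tuple[float, float, float] = (3.0, 0.5, 0.5)
    noise_sigma: float = 0.0
    test_fraction: float = 0.2
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    mvsc: MvscConfig = field(default_factory=MvscConfig)
    write_nifti: bool = False  # persist cohort volumes/masks alongside reports

    def fingerprint(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class CaseReport:
    """One scored case: quantification result plus provenance and warnings."""

    case_id: str
    provenance: str  # automatic | manual
    result: CacsResult
    warnings: list[str] = field(default_factory=list)
    config_fingerprint: str = ""

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "provenance": self.provenance,
            "result": self.result.to_dict(),
            "warnings": list(self.warnings),
            "config_fingerprint": self.config_fingerprint,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CaseReport":
        r = d["result"]
        result = CacsResult(
            agatston=r["agatston"], volume=r["volume_mm3"], mass=r["mass_mg"],
            calcified_vessels=tuple(r["calcified_vessels"]),
            n_vessels=r["n_vessels"], a_category=r["a_category"],
            n_category=r["n_category"],
        )
        return cls(case_id=d["case_id"], provenance=d["provenance"],
                   result=result, warnings=list(d.get("warnings", [])),
                   config_fingerprint=d.get("config_fingerprint", ""))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _dump_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def score_with_warnings(vol: CtVolume, mask: VesselLabelMask,
                        cfg: ScoringConfig) -> tuple[CacsResult, list[str]]:
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = score_case(vol, mask, cfg)
    return result, [str(w.message) for w in caught]


def split_cohort(n: int, seed: int, test_fraction: float = 0.2
                 ) -> tuple[list[int], list[int]]:
    """Seeded by-case shuffle split; returns (train indices, test indices)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    test = sorted(int(i) for i in order[:n_test])
    train_idx = sorted(int(i) for i in order[n_test:])
    return train_idx, test


def run_end_to_end(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Phantom cohort -> train -> predict -> score both arms -> agreement.

    Writes per-case reports, the agreement report, a markdown summary, and a
    JSON-lines run log under ``out_dir``; returns ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run_log.jsonl"
    fingerprint = cfg.fingerprint()

    def log(stage: str, **info) -> None:
        entry = {"stage": stage, "time": time.time(),
                 "seed": cfg.seed, "config": fingerprint, **info}
        with open(log_path, "a") as fh:
            fh.write(json.dumps(entry) + "\n")

    t0 = time.time()
    cohort = standard_cohort(cfg.n_cases, seed=cfg.seed, shape=cfg.shape,
                             spacing=cfg.spacing, noise_sigma=cfg.noise_sigma)
    log("phantom", n_cases=cfg.n_cases, elapsed_s=time.time() - t0)
    if cfg.write_nifti:
        write_cohort(cohort, out_dir / "cohort")

    train_idx, test_idx = split_cohort(cfg.n_cases, cfg.seed + 1,
                                       cfg.test_fraction)
    t0 = time.time()
    mvsc_cfg = MvscConfig(**{**asdict(cfg.mvsc), "seed": cfg.seed + 2})
    model = train([cohort[i] for i in train_idx], mvsc_cfg)
    model.save(out_dir / "model")
    log("train", n_train=len(train_idx), elapsed_s=time.time() - t0)

    t0 = time.time()
    reports: list[CaseReport] = []
    auto_scores: dict[str, CacsResult] = {}
    manual_scores: dict[str, CacsResult] = {}
    reg_estimates: dict[str, dict] = {}
    seg_quality: dict[str, dict] = {}
    for i in test_idx:
        case = cohort[i]
        cid = case.record.case_id
        pred = predict_mask(model, case.volume)
        auto_result, auto_warn = score_with_warnings(case.volume, pred,
                                                     cfg.scoring)
        manual_result, man_warn = score_with_warnings(case.volume, case.mask,
                                                      cfg.scoring)
        auto_scores[cid] = auto_result
        manual_scores[cid] = manual_result
        reg_estimates[cid] = predict_scores(model, case.volume)
        seg_quality[cid] = {
            "f1": agreement.f1_per_vessel(pred, case.mask),
            "confuser_leak": agreement.confuser_leak_fraction(pred, case.mask),
        }
        reports.append(CaseReport(cid, "automatic", auto_result, auto_warn,
                                  fingerprint))
        reports.append(CaseReport(cid, "manual", manual_result, man_warn,
                                  fingerprint))
    log("score", n_test=len(test_idx), elapsed_s=time.time() - t0)

    for report in reports:
        _dump_json(report.to_dict(),
                   out_dir / "reports" / f"{report.case_id}_{report.provenance}.json")

    auto_df = agreement.scores_to_long(auto_scores, "automatic")
    manual_df = agreement.scores_to_long(manual_scores, "manual")
    battery = agreement.run_battery(auto_df, manual_df)
    battery["segmentation"] = seg_quality
    battery["regression_estimates"] = reg_estimates
    battery["split"] = {"train": [cohort[i].record.case_id for i in train_idx],
                        "test": [cohort[i].record.case_id for i in test_idx]}
    _dump_json(battery, out_dir / "reports" / "agreement.json")

    summary = render_report(
        [r for r in reports if r.provenance == "automatic"], battery)
    (out_dir / "reports" / "summary.md").write_text(summary)
    log("done")
    return out_dir


# ---------------------------------------------------------------------------
# Rendering

_LEVELS = ("Total", "LM", "LAD", "LCX", "RCA")


def render_report(reports: list[CaseReport], battery: dict | None = None) -> str:
    """Markdown summary: one score block per case, then agreement statistics.

    Rendering is a pure function of the report objects; every number shown
    is present in the JSON artifacts.
    """
    if not reports:
        raise ValueError("render_report needs at least one case report")
    lines: list[str] = ["# Calcium scoring report", ""]
    for report in reports:
        r = report.result
        lines += [f"## {report.case_id} ({report.provenance})", "",
                  "| Level | AS | VS (mm^3) | MS (mg) |",
                  "|-------|-----|-----------|---------|"]
        for level in _LEVELS:
            lines.append(f"| {level} | {r.agatston[level]:.2f} "
                         f"| {r.volume[level]:.2f} | {r.mass[level]:.3f} |")
        lines += ["",
                  f"Calcified vessels: {', '.join(r.calcified_vessels) or 'none'} "
                  f"(n = {r.n_vessels}); CAC-DRS {r.a_category}/{r.n_category}",
                  ""]
        for w in report.warnings:
            lines.append(f"> warning: {w}")
        if report.warnings:
            lines.append("")
    if battery is None or not battery.get("continuous"):
        lines += ["_Agreement section omitted: only one arm present._", ""]
        return "\n".join(lines)
    lines += ["## Automatic vs manual agreement", "",
              "| Measure/Level | n | ICC | mean diff | 95% LoA | paired-t p |",
              "|---------------|---|-----|-----------|---------|------------|"]
    for key, entry in battery["continuous"].items():
        ba = entry["bland_altman"]
        icc_val = entry["icc"].get("icc")
        icc_txt = f"{icc_val:.3f}" if icc_val is not None else "n/a"
        p_txt = f"{entry['paired_t']['p']:.3f}"
        lines.append(
            f"| {key} | {entry['n']} | {icc_txt} | {ba['mean_diff']:.2f} "
            f"| ({ba['loa_low']:.2f}, {ba['loa_high']:.2f}) | {p_txt} |")
    if battery.get("mcnemar"):
        lines += ["", "| Vessel | auto + | manual + | McNemar p |",
                  "|--------|--------|----------|-----------|"]
        for vessel, entry in battery["mcnemar"].items():
            lines.append(f"| {vessel} | {entry['n_auto']} | {entry['n_manual']} "
                         f"| {entry['p']:.3f} |")
    lines.append("")
    return "\n".join(lines)
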