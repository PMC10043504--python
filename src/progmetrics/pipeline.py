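"""End-to-end pipeline: simulate/load -> filter -> thresholds -> classify -> evaluate.

Every random step derives from a single seed, so re-running a configuration
reproduces every artifact byte-identically.  All intermediate artifacts are
plain CSV, so each stage can also be re-run independently from its
serialized upstream outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import cohort as co
from . import simulate as sim
from .decision import decisions_to_frame, status_map
from .event import classify_event_all
from .metrics import metric_names
from .performance import fp_comparison_table, performance_table
from .rules import builtin_rules, evaluate_rules_all, load_rules_file
from .thresholds import ThresholdBank
from .trend import classify_trend_all

log = logging.getLogger("progmetrics")

PAPER_LEVELS_TAU = (0.05, 0.025)
PAPER_LEVELS_ALPHA = (0.05, 0.025, 0.01)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    cohort_path: str | None = None        # long-format CSV; None -> simulate
    retest_path: str | None = None        # retest CSV; None -> simulate
    generator: sim.GeneratorConfig = field(default_factory=sim.GeneratorConfig)
    tau: float = 0.025
    alpha: float = 0.05
    mode: str = "both"                    # event | trend | both
    comparison: str = "first_vs_last"
    rules_file: str | None = None
    missing_as_stable: bool = False
    bootstrap_B: int = 1000
    seed: int = 0
    paper_literal: bool = False
    allow_any_level: bool = False
    metrics: tuple[str, ...] | None = None
    outdir: str = "progmetrics_out"

    def validate(self) -> None:
        if self.mode not in ("event", "trend", "both"):
            raise ValueError(f"bad mode {self.mode!r}")
        if not self.allow_any_level:
            if self.tau not in PAPER_LEVELS_TAU:
                raise ValueError(
                    f"tau {self.tau} not in {PAPER_LEVELS_TAU}; pass allow_any_level"
                )
            if self.alpha not in PAPER_LEVELS_ALPHA:
                raise ValueError(
                    f"alpha {self.alpha} not in {PAPER_LEVELS_ALPHA}; pass allow_any_level"
                )


def run_pipeline(cfg: RunConfig) -> dict[str, object]:
    """Run every stage and write the artifact bundle to ``cfg.outdir``.

    Returns the in-memory artifacts (cohort, threshold bank, decision
    tables, performance frames) keyed by name.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    gen = dataclasses.replace(cfg.generator, seed=cfg.seed)

    truth = None
    if cfg.cohort_path:
        cohort = co.load_cohort(cfg.cohort_path)
        log.info("loaded cohort from %s: %d eyes", cfg.cohort_path, len(cohort))
    else:
        cohort, truth = sim.generate_cohort(gen)
        log.info("simulated cohort: %d eyes (seed=%d)", len(cohort), cfg.seed)
        co.write_cohort(cohort, outdir / "cohort.csv")
        sim.truth_to_frame(truth).to_csv(outdir / "ground_truth.csv", index=False)

    if cfg.retest_path:
        retest = co.load_cohort(cfg.retest_path)
    else:
        retest = sim.generate_test_retest_set(gen)
        co.write_cohort(retest, outdir / "retest.csv")

    cohort, exclusions = co.apply_vf_quality_filter(cohort)
    retest, retest_exclusions = co.apply_vf_quality_filter(retest)
    co.exclusions_to_frame(exclusions + retest_exclusions).to_csv(
        outdir / "vf_exclusions.csv", index=False
    )
    log.info("VF quality filter: %d visit exclusions", len(exclusions) + len(retest_exclusions))

    if cfg.metrics:
        names = list(cfg.metrics)
    elif cfg.cohort_path is None:
        names = list(gen.metrics)   # simulated cohorts carry only these metrics
    else:
        names = metric_names()
    bank = ThresholdBank.fit(
        retest, names, taus=(cfg.tau,), paper_literal=cfg.paper_literal
    )
    bank.to_csv(outdir / "thresholds.csv")

    rules = builtin_rules()
    if cfg.rules_file:
        rules.update(load_rules_file(cfg.rules_file))
    usable_rules = {
        n: r for n, r in rules.items()
        if all(leaf in names for leaf in _leaves(r))
    }

    artifacts: dict[str, object] = {
        "cohort": cohort,
        "truth": truth,
        "bank": bank,
    }

    if cfg.mode in ("event", "both"):
        ev = classify_event_all(
            cohort, bank, cfg.tau, names, cfg.comparison, paper_literal=cfg.paper_literal
        )
        ev_rules = evaluate_rules_all(ev, usable_rules, missing_as_stable=cfg.missing_as_stable)
        decisions_to_frame(ev).to_csv(outdir / "decisions_event.csv", index=False)
        decisions_to_frame(ev_rules).to_csv(outdir / "decisions_event_rules.csv", index=False)
        maps = {n: status_map(ev, n) for n in names}
        maps |= {n: status_map(ev_rules, n) for n in usable_rules}
        perf_ev = performance_table(maps, cohort, B=cfg.bootstrap_B, seed=cfg.seed)
        perf_ev.to_csv(outdir / "performance_event.csv", index=False)
        artifacts |= {"event": ev, "event_rules": ev_rules, "performance_event": perf_ev}

    if cfg.mode in ("trend", "both"):
        tr = classify_trend_all(cohort, cfg.alpha, names, paper_literal=cfg.paper_literal)
        tr_rules = evaluate_rules_all(tr, usable_rules, missing_as_stable=cfg.missing_as_stable)
        decisions_to_frame(tr).to_csv(outdir / "decisions_trend.csv", index=False)
        decisions_to_frame(tr_rules).to_csv(outdir / "decisions_trend_rules.csv", index=False)
        maps = {n: status_map(tr, n) for n in names}
        maps |= {n: status_map(tr_rules, n) for n in usable_rules}
        perf_tr = performance_table(maps, cohort, B=cfg.bootstrap_B, seed=cfg.seed)
        perf_tr.to_csv(outdir / "performance_trend.csv", index=False)
        artifacts |= {"trend": tr, "trend_rules": tr_rules, "performance_trend": perf_tr}

    if cfg.mode == "both":
        ev_maps = {n: status_map(artifacts["event"], n) for n in names}
        ev_maps |= {n: status_map(artifacts["event_rules"], n) for n in usable_rules}
        tr_maps = {n: status_map(artifacts["trend"], n) for n in names}
        tr_maps |= {n: status_map(artifacts["trend_rules"], n) for n in usable_rules}
        comp = fp_comparison_table(
            tr_maps, ev_maps, cohort, list(ev_maps), B=cfg.bootstrap_B, seed=cfg.seed
        )
        comp.to_csv(outdir / "fp_comparison.csv", index=False)
        artifacts["fp_comparison"] = comp

    return artifacts


def _leaves(rule) -> list[str]:
    from .rules import rule_leaves

    return rule_leaves(rule)
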