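"""Case-control statistics, result-table assembly, and pipeline orchestration.

All across-subject comparisons use two-tailed tests: Pearson chi-square
without continuity correction for proportion tables, Welch's t for unequal
variances, Wilcoxon signed-rank for paired/one-sample comparisons, and
Spearman rank correlation. Multiple comparisons follow the protocol
(uncorrected, test by test) with an optional Benjamini-Hochberg layer.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cognophen.errors import DataError

log = logging.getLogger("cognophen")


@dataclass
class ContingencyTable:
    """2x2 counts of group x trait."""

    counts: np.ndarray
    group_labels: tuple[str, str] = ("group1", "group2")
    trait_labels: tuple[str, str] = ("yes", "no")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2):
            raise DataError("ContingencyTable must be 2x2")
        if np.any(self.counts < 0):
            raise DataError("negative counts")
        if np.any(self.counts.sum(axis=0) == 0) or np.any(self.counts.sum(axis=1) == 0):
            raise DataError("zero margin: chi-square undefined")


def proportion_chi_square(t: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test of equal proportions, df = 1, no continuity
    correction (matching how the published 2x2 comparisons were computed).
    Returns (chi2, df, p)."""
    chi2, p, df, _ = stats.chi2_contingency(t.counts, correction=False)
    return float(chi2), int(df), float(p)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, Satterthwaite df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DataError("Welch test needs >= 2 observations per sample")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def wilcoxon_signed_rank(x, mu: float = 0.0) -> tuple[float, float]:
    """Two-tailed Wilcoxon signed-rank test of symmetry about ``mu``.

    The exact null distribution is used for n <= 25 without ties; larger
    samples use the normal approximation with tie correction.
    """
    d = np.asarray(x, dtype=float) - mu
    d = d[d != 0]
    if d.size == 0:
        raise DataError("Wilcoxon needs at least one nonzero difference")
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-tailed p; constant input flagged."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DataError("spearman undefined for constant input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (optional, non-default layer)."""
    _, q, _, _ = multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")
    return q


def result_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble a generic result table (comparison, statistic, value, p, n)."""
    df = pd.DataFrame(rows)
    if "p" in df.columns and len(df):
        bad = df["p"].dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise DataError("p-values outside [0, 1]")
    return df


def round_p_display(p: float, ndigits: int = 3) -> float:
    """Display rounding of p-values (full precision is kept in JSON)."""
    return float(np.round(p, ndigits))


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run the configured stages end to end on synthetic inputs and write
    the result bundle (CSV tables, ``summary.json``, ``run.log``).

    ``config`` keys: ``seed`` (int) and ``stages`` (subset of
    {"behavior", "units", "geno", "conn"}; default all). The summary is
    deterministic for a fixed seed.
    """
    from cognophen import behavior, conn, geno, units
    from cognophen.epochs import DEFAULT_EPOCHS, EpochSpec
    from cognophen.syndata import (SimConfig, case_control_fixture, gen_coupled_lfp,
                                   gen_reversal_sessions, gen_units)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", ["behavior", "units", "geno", "conn"])
    summary: dict = {"seed": seed, "stages": list(stages), "excluded": {}}

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("pipeline start: seed=%d stages=%s", seed, stages)

    try:
        if "behavior" in stages:
            cfg = SimConfig(seed=seed, policy="optimal_social", n_blocks=60)
            trials = gen_reversal_sessions(cfg)
            curve = behavior.score_switch_response(trials)
            curve.to_csv(outdir / "score_curve.csv")
            summary["behavior"] = {
                "trial2_mean_score": float(curve.loc[2, "mean_score"]),
                "n_trials": int(len(trials)),
            }
            summary["excluded"]["first_block_trials"] = \
                curve.attrs["n_excluded_first_block"]

        if "units" in stages:
            mirror_cfg = SimConfig(seed=seed, rate_offset_self=8.0, rate_offset_partner=8.0)
            self_cfg = SimConfig(seed=seed + 1, rate_offset_self=10.0)
            cohort = gen_units(mirror_cfg, n_units=10) + gen_units(self_cfg, n_units=10)
            labels = [units.classify_actor_unit(u) for u in cohort]
            for lab in labels:
                lab.subject = "SYN"
            table = units.type_proportion_table(labels)
            table.to_csv(outdir / "type_proportions.csv", index=False)
            summary["units"] = {
                "n_units": len(labels),
                "n_mirror": int(sum(l.label == "mirror" for l in labels)),
                "n_self": int(sum(l.label == "self" for l in labels)),
            }

        if "geno" in stages:
            gm, variants = case_control_fixture()
            res = geno.screen_variants(
                gm, variants, cases=["M593", "M639", "M344"],
                controls=["M1486", "M1488", "M1140", "M1969"],
                annotation_model="NCBI-103",
            )
            res.table.to_csv(outdir / "screen.tsv", sep="\t", index=False)
            summary["geno"] = {
                "n_hits": len(res.hits),
                "hit_genes": sorted(v.gene for v in res.hits),
            }

        if "conn" in stages:
            cfg = SimConfig(seed=seed, n_contacts=3, n_lfp_trials=30,
                            trial_dur_ms=1600.0, event_ms=400.0,
                            coupling_direction="top_down", coupling_strength=0.5)
            a, b = gen_coupled_lfp(cfg)
            window = EpochSpec("stimulus", 0, 1000, align="stimulus_onset")
            gc = conn.pairwise_gc(a, b, window, conn.GCParams(max_order=8))
            fb = conn.flow_bias(gc)
            gc.to_csv(outdir / "gc_pairs.csv", index=False)
            (outdir / "flow_bias.json").write_text(json.dumps({
                "prop_top_down": fb.prop_top_down,
                "prop_bottom_up": fb.prop_bottom_up,
                "bias": fb.bias,
                "n_pairs": fb.n_pairs,
            }, indent=2))
            summary["conn"] = {"flow_bias": fb.bias, "n_pairs": fb.n_pairs}
            summary["excluded"]["gc_pairs"] = int(gc["excluded"].sum() // 2)
    except KeyError as e:  # missing stage input
        raise DataError(f"missing input for stage: {e}") from e
    finally:
        log.removeHandler(handler)
        handler.close()

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
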