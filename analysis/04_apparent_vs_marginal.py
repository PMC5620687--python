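"""Contrast risk forecasts built from apparent mortality vs marginal attack rates.

Apparent mortality — the raw proportion parasitized in field samples — carries
no competing-mortality context, so forecasts built from it overstate
generational impact relative to forecasts built from life-table marginal
attack rates.  This driver runs the packaged contrast for T. flavoorbitalis
(2000 trials through the worst-case tree from each dataset), reports the 0.40
control-threshold exceedance of the apparent forecast both by Monte Carlo and
by direct counting, the rank-sum test between the two forecasts, and the
zero-count audit that rules out fitted distributions for the other two agents.

Writes results/study/ (study_report.json, forecast CSVs).
"""

from pathlib import Path

from biopra import reproduce_study

OUT = Path(__file__).resolve().parents[1] / "results" / "study"


def main() -> None:
    report = reproduce_study(output_dir=OUT, seed=0, n_trials=2000)

    app = report["apparent"]
    print(f"apparent-mortality forecast: mean {app['forecast_summary']['mean']:.4f}, "
          f"range [{app['forecast_summary']['min']:.3f}, {app['forecast_summary']['max']:.3f}]")
    print(f"P(apparent forecast > 0.40): {app['exceedance_0.40_monte_carlo']:.4f} "
          f"(Monte Carlo, beta fit) vs {app['exceedance_0.40_empirical_count']:.2f} "
          f"(direct count of table values)")
    marg = report["marginal"]["forecast_summary"]
    print(f"marginal-rate forecast: mean {marg['mean']:.4f}, "
          f"range [{marg['min']:.3f}, {marg['max']:.3f}]")
    cmp = report["apparent_vs_marginal"]
    print(f"rank-sum apparent vs marginal: T={cmp['rank_sum_T']:.0f}, "
          f"z={cmp['z']:.1f}, p={cmp['p_two_sided']:.3g} "
          f"-> apparent mortality significantly inflates the risk estimate")
    print(f"dominance at 5/25/50/75/95th percentiles: "
          f"{all(cmp['percentile_dominance'].values())}")
    for agent, audit in report["table5_zero_counts"].items():
        print(f"{agent}: {audit['zeros']} of {audit['n']} marginal attack rates are "
              f"zero -> no distribution can be fitted")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
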