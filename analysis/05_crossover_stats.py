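#!/usr/bin/env python
"""Crossover statistics on the measured outcome table.

Per outcome: within-block paired t-tests ("effect of time"), the
baseline-adjusted ANCOVA treatment comparison (INCO vs AIR), and the
change-score ANOVA — the same surface a crossover training study reports.
"""

from pathlib import Path

import pandas as pd

from colhtl.stats import ancova_treatment, change_anova, change_scores, summarize_changes
from colhtl.tableio import CROSSOVER_SCHEMA, read_table

OUT = Path(__file__).resolve().parents[1] / "results"

UNITS = {
    "hbmass_g": "g", "hbmass_rel": "g/kg", "rbcv_ml": "mL", "pv_ml": "mL",
    "bv_ml": "mL", "k_min": "min^-1", "speed4_ms": "m/s", "speed2_ms": "m/s",
    "la_max_mm": "mM",
}


def main() -> None:
    table = read_table(OUT / "crossover_table.csv", CROSSOVER_SCHEMA)
    rows = []
    for outcome in sorted(table.outcome.unique()):
        eff = ancova_treatment(table, outcome)
        _, p_anova = change_anova(table, outcome)
        ch = summarize_changes(change_scores(table, outcome))
        rows.append(dict(
            outcome=outcome, unit=UNITS.get(outcome, ""),
            inco_change=round(ch.loc["INCO", "mean_change"], 2),
            inco_pct=round(ch.loc["INCO", "mean_pct"], 2),
            air_change=round(ch.loc["AIR", "mean_change"], 2),
            air_pct=round(ch.loc["AIR", "mean_pct"], 2),
            effect=round(eff.effect, 3), se=round(eff.se, 3),
            p_time_inco=round(eff.p_time_inco, 4),
            p_time_air=round(eff.p_time_air, 4),
            p_treatment=round(eff.p_treatment, 4),
            p_change_anova=round(p_anova, 4),
            n_inco=eff.n_inco, n_air=eff.n_air,
        ))
    out_df = pd.DataFrame(rows)
    out_df.to_csv(OUT / "treatment_effects.csv", index=False)

    print("outcome          effect(SE)           p_treat  p_time_INCO")
    for r in rows:
        print(f"{r['outcome']:<16} {r['effect']:+10.2f} ({r['se']:.2f})  "
              f"{r['p_treatment']:.3f}    {r['p_time_inco']:.3f}")
    sig = [r["outcome"] for r in rows if r["p_treatment"] < 0.05]
    print(f"treatment effects at p<0.05: {', '.join(sig) if sig else 'none'}")
    print(f"wrote {OUT / 'treatment_effects.csv'}")


if __name__ == "__main__":
    main()
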