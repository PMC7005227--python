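#!/usr/bin/env python
"""Detriment-adjusted risk per radiograph, with and without gonad shields,
for each historical epoch; plus the break-even incident rate that would
offset today's shielding benefit.

Writes results/risk_table.csv (per-million risks).
"""

from pathlib import Path

from pelvidose import io
from pelvidose.risk_model import breakeven_incident_rate, build_risk_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = io.load_table(io.packaged_fixture("table3_doses.csv"), "doses")
    table = build_risk_table(rows)
    io.write_report(table, RESULTS / "risk_table.csv")

    print(f"{'epoch':38s} {'male':>18s} {'female':>18s}   (per 1e6, unshielded -> shielded)")
    for male, female in table:
        print(
            f"{male.label:38s} "
            f"{1e6 * male.risk_unshielded:7.1f} -> {1e6 * male.risk_shielded:6.1f} "
            f"{1e6 * female.risk_unshielded:7.1f} -> {1e6 * female.risk_shielded:6.1f}"
        )

    male_2018, female_2018 = table[-1]
    print(
        f"\n2018 shielding benefit: male {1e6 * male_2018.reduction:.1f}, "
        f"female {1e6 * female_2018.reduction:.2f} per million radiographs"
    )
    for harm in (1.0, 0.1):
        rate = breakeven_incident_rate(male_2018.reduction, harm)
        print(
            f"  at {harm:g} detriment-equivalent harm per incident, "
            f"{rate:.1f} incidents per million radiographs cancel the male benefit"
        )


if __name__ == "__main__":
    main()
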