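#!/usr/bin/env python
"""Common m-value and double-mutant-cycle coupling energies.

Averages the m-values of the six cycle variants (wild-type, L49I, D55G,
I57V, D55G/I57V, L49I/I57V) and computes the coupling energy dddG_f of both
double-mutant cycles from the published common-m ddG_f records. Writes
results/double_mutant_cycles.csv.
"""

from pathlib import Path

import pandas as pd

from foldstab import (
    StabilityRecord,
    average_m,
    coupling_energy,
    reference_params,
    reference_record,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "double_mutant_cycles.csv"
SIX = ["wild-type", "L49I", "D55G", "I57V", "D55G/I57V", "L49I/I57V"]


def record(label: str) -> StabilityRecord:
    rec = reference_record(label)
    return StabilityRecord(
        label, float(rec["ddg_common_m"]), float(rec["ddg_common_m_se"]), "common-m"
    )


def main() -> None:
    m = average_m([reference_params(v).m_value for v in SIX])
    print(f"common m-value (mean of {len(SIX)} variants): {m:.2f} kJ/mol/M\n")

    rows = []
    for s1, s2, dbl in [("D55G", "I57V", "D55G/I57V"), ("L49I", "I57V", "L49I/I57V")]:
        cyc = coupling_energy(record(s1), record(s2), record(dbl))
        sign = "unfavourable" if cyc.dddg > 0 else "favourable"
        print(
            f"{dbl:12s} cycle: dddG = {cyc.dddg:+.2f} ± {cyc.dddg_se:.2f} kJ/mol "
            f"({sign} synergy)"
        )
        rows.append(
            {
                "single_1": s1, "single_2": s2, "double": dbl,
                "ddg_1": record(s1).dg, "ddg_2": record(s2).dg,
                "ddg_double": record(dbl).dg,
                "dddg": round(cyc.dddg, 3), "dddg_se": round(cyc.dddg_se, 3),
            }
        )
    OUT.parent.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT, index=False)
    print(f"\nwrote {OUT}")


if __name__ == "__main__":
    main()
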