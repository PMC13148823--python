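#!/usr/bin/env python
"""Extract per-state oxygen fluxes and coupling metrics from the cohort.

Finding: tumors respire several-fold faster than benign tissue per mg wet
weight across the whole substrate ladder, and oligomycin inhibits tumor
respiration more strongly (~80% vs ~55%) — tumor mitochondria are more,
not less, coupled.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

from mitoflux import syndata
from mitoflux.config import study_preset
from mitoflux.respiro import build_state_table, coupling_metrics

SEED = 1


def main() -> None:
    cfg = study_preset(SEED)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    bio, rep = build_state_table(
        syndata.simulate_respirometry(cfg, "CI_CII_coupling", SEED))
    bio.to_csv(results / "state_table_wet_weight.csv", index=False)

    ladder = bio.groupby(["group", "state"])["jo2"].agg(["mean", "std"]).round(2)
    print("per-state JO2 (pmol O2 s-1 mg-1 wet weight):")
    print(ladder)

    cm = coupling_metrics(bio)
    cm.to_csv(results / "coupling_metrics.csv", index=False)
    med = cm.groupby("group")[["omy_inhibition_pct", "residual_pct"]].median().round(1)
    print("\nmedian coupling metrics:")
    print(med)

    lipid, _ = build_state_table(syndata.simulate_respirometry(cfg, "LIPID", SEED))
    lipid.to_csv(results / "state_table_lipid.csv", index=False)
    mdpc = lipid[lipid.state == "MDPC"].groupby("group")["jo2"].mean()
    print(f"\nlipid-supported (MDPC) tumor/benign ratio: "
          f"{mdpc['tumor'] / mdpc['benign']:.1f}x")


if __name__ == "__main__":
    sys.exit(main())
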