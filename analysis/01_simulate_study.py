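#!/usr/bin/env python
"""Generate the synthetic benign-vs-tumor study and inventory its parts.

Writes the raw study inputs (respirometry trace files, proteome/TPM
matrices, annotation, Bradford and cell-type tables) under
scratch/study/ and prints what was generated.  Downstream analysis
scripts re-derive what they need deterministically from the same preset,
so this script is for inspection, not a required predecessor.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

from mitoflux import annotation as ann_mod
from mitoflux import io as mio
from mitoflux import respiro, syndata
from mitoflux.config import study_preset

SEED = 1


def main() -> None:
    out = ROOT / "scratch" / "study"
    cfg = study_preset(SEED)
    traces = syndata.simulate_respirometry(cfg, "CI_CII_coupling", SEED)
    for tr in traces:
        respiro.write_trace(tr, out / "traces")
    sim = syndata.simulate_proteome(cfg, SEED)
    mio.write_abundance(sim.abundance, out / "proteome.csv")
    ann_mod.write_annotation(sim.annotation, out / "annotation.tsv")
    sim.truth.to_csv(out / "proteome_truth.csv", index=False)
    tpm = syndata.simulate_transcriptome(cfg, SEED)
    mio.write_abundance(tpm, out / "tpm.csv")
    expr, props = syndata.simulate_celltype_tables(cfg, SEED)
    expr.to_csv(out / "celltype_expression.csv", index=False)
    props.to_csv(out / "celltype_proportions.csv", index=False)
    syndata.simulate_bradford(cfg, SEED).to_csv(out / "bradford.csv", index=False)

    n_bio = sum(g.n_samples for g in cfg.groups.values())
    print(f"simulated {len(traces)} traces ({n_bio} biological samples x "
          f"{cfg.n_technical_replicates} technical replicates)")
    print(f"proteome: {cfg.n_features} features x "
          f"{sim.abundance.values.shape[1]} samples, "
          f"{sim.abundance.values.isna().to_numpy().mean():.0%} missing")
    print(f"transcriptome: {tpm.values.shape[0]} genes, columns sum to 1e6")
    print(f"raw study written under {out}")


if __name__ == "__main__":
    sys.exit(main())
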