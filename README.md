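# mitoflux

Bioenergetic analysis of HER2-driven mammary tumors versus benign mammary
tissue, built as a tested, reusable pipeline. The package is for
physiologists and cancer-metabolism researchers who need to answer a
deceptively simple question: when a tumor respires faster per milligram of
tissue, is that because its mitochondria work harder, or because there are
more of them?

## What it computes

**Respirometry.** SUIT-protocol (substrate–uncoupler–inhibitor titration)
oxygen traces are segmented at injection events into composite respiratory
states (E → PM → PMD → PMDG → PMDGS, then OMY / AMA+ROT), and the oxygen
flux per state is the ordinary-least-squares slope of the O2 concentration:

    JO2 = −slope(O2 vs t) · V_chamber · 1000 / amount   [pmol O2 s⁻¹ mg⁻¹]

Technical replicates are averaged per biological sample. Coupling metrics
follow: oligomycin inhibition 100·(1 − J_OMY/J_PMDGS), the
antimycin A + rotenone residual, and the cytochrome c test.

**Normalization.** Each flux table can be expressed per mg wet weight, per
µg total protein (group-mean Bradford factor), or per mitochondrial content
using the mitochondrial enrichment factor

    MEF = Σ abundance(MitoCarta-flagged proteins) / Σ abundance(all proteins),

computed per sample from label-free proteomics and averaged per group.
MEF-normalized flux = total-protein-normalized flux / group MEF. H2O2
emission rates (Amplex Red standard-curve calibration) run through the same
three schemes.

**Omics.** Detection Venn logic under dropout, a Welch-t + Benjamini–
Hochberg differential-abundance stand-in (padj < 0.1), summed mitochondrial
abundance, per-complex OXPHOS subunit summaries against mito or total
denominators, and transcript–protein log2FC integration (Pearson r, joint
down/down and up/up overlap sets).

**Cell-type scoring.** The OXPHOS mRNA Index per respiratory complex,
Index = %Expression_CT × %Immunopositive_CT, where %Expression_CT is the
atlas-proportion-weighted mean percent of cells expressing each complex's
subunits, and the Total OXPHOS mRNA Score sums the index over Complexes
I–V.

**Statistics.** Welch/Student t, Cohen's d, CV%, BH FDR, Pearson, and
noncentral-t two-sample power (ncp = d·√(n/2), df = 2n − 2).

Every input can be produced by the synthetic-study generator
(`mitoflux.syndata`), which encodes the study conditions as a versioned
preset — so the whole pipeline is testable without any external data.

## Worked example

```python
from mitoflux.config import study_preset
from mitoflux import syndata
from mitoflux.respiro import build_state_table, coupling_metrics
from mitoflux.normalize import NormalizationFactors, apply_normalization, \
    compute_mef, protein_factor

cfg = study_preset(seed=1)
traces = syndata.simulate_respirometry(cfg, "CI_CII_coupling", seed=1)
bio, _ = build_state_table(traces)

sim = syndata.simulate_proteome(cfg, seed=1)
mef, _ = compute_mef(sim.abundance, sim.annotation)
factors = NormalizationFactors(
    protein_ug_per_mg=protein_factor(syndata.simulate_bradford(cfg, 1)),
    mef=mef,
)

ww = bio[bio.state == "PMDGS"].groupby("group")["jo2"].mean()
me = apply_normalization(bio, "mef", factors)
mm = me[me.state == "PMDGS"].groupby("group")["jo2"].mean()
print(f"wet-weight tumor/benign: {ww['tumor']/ww['benign']:.2f}")
print(f"MEF-normalized tumor/benign: {mm['tumor']/mm['benign']:.2f}")
print(coupling_metrics(bio).groupby("group")["omy_inhibition_pct"].median())
```

prints

```
wet-weight tumor/benign: 7.94
MEF-normalized tumor/benign: 4.30
group
benign    54.703775
tumor     80.347468
Name: omy_inhibition_pct, dtype: float64
```

Read: tumors respire ~8-fold faster per mg of tissue; after dividing out
total protein and mitochondrial content the difference shrinks to ~4-fold
but does not vanish — the increase is intrinsic to tumor mitochondria, not
a content artifact — and oligomycin inhibits ~80% of tumor respiration
versus ~55% in benign tissue, so tumor mitochondria are the more coupled.

The numbered scripts under `analysis/` run the full narrative
(simulation → flux extraction → normalization → omics integration →
cell-type scoring → power) and write their tables under `results/`.
A `mitoflux` console command exposes the same steps for shell use
(`mitoflux simulate --out DIR`, `mitoflux respiro`, `mitoflux normalize`,
`mitoflux omics-integrate`, `mitoflux ctindex`, `mitoflux power`).

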