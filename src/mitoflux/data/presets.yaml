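# Versioned benign-vs-tumor study preset.
#
# Ground-truth fluxes are pmol O2 s-1 mg-1 wet weight.  The tumor/benign
# PMDGS ratio is 7.0 (within the reported 4.9-9.9x wet-weight range) and the
# lipid-protocol MDPC ratio is 8.3.  Oligomycin coupling fractions are 0.80
# (tumor) and 0.55 (benign); antimycin A + rotenone leave a 2% residual.
# Tissue amounts follow the chamber loadings (2-5 mg tumor, 15-20 mg benign);
# benign mammary tissue is adipose-rich, hence its much lower total protein
# per mg wet weight.  Tumor mitochondrial protein content is scaled to 0.65
# of benign, so the mitochondrial enrichment factor falls in tumors while the
# flux per unit mitochondrial protein rises.
version: 1
n_features: 1000
frac_mito: 0.15
abundance_sigma: 0.25
chamber_volume_ml: 2.0
o2_start_uM: 180.0
dt_s: 2.0
state_duration_s: 240.0
n_technical_replicates: 2
seed: 0
groups:
  benign:
    n_samples: 20
    n_omics_samples: 6
    amount_mg: 18.0
    noise_sd: 0.2
    biological_cv: 0.30
    coupling_fraction: 0.55
    residual_fraction: 0.02
    true_jo2:
      E: 1.0
      PM: 2.5
      PMD: 6.0
      PMDG: 7.0
      PMDGS: 10.0
      M: 1.5
      MD: 2.0
      MDPC: 6.0
    content_scale: 1.0
    mito_log2fc: 0.0
    complex_log2fc: {}
    detection_dropout_rate: 0.25
    protein_ug_per_mg: 40.0
    protein_cv: 0.10
  tumor:
    n_samples: 20
    n_omics_samples: 6
    amount_mg: 3.0
    noise_sd: 0.2
    biological_cv: 0.30
    coupling_fraction: 0.80
    residual_fraction: 0.02
    true_jo2:
      E: 6.0
      PM: 15.0
      PMD: 40.0
      PMDG: 50.0
      PMDGS: 70.0
      M: 8.0
      MD: 10.0
      MDPC: 50.0
    content_scale: 0.65
    mito_log2fc: 0.0
    complex_log2fc:
      CI: -1.0
      CII: -0.8
      CIII: -1.0
      CIV: -0.9
      CV: -0.6
    detection_dropout_rate: 0.25
    protein_ug_per_mg: 100.0
    protein_cv: 0.10
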