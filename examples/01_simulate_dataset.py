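"""Simulate a small RNA-seq + DNA-depth dataset with a known dosage model.

The generator plants the truth we later try to recover: X-specific genes
at 0.7x dose in XY males, a pseudoautosomal region (PAR) at parity, and
X/Y gametologue pairs whose summed output is conserved.
"""

from pathlib import Path

import dosagecomp as dc

cfg = dc.SimulationConfig(
    n_autosomal=1000, n_x_specific=120, n_par=20, n_xy_shared=20,
    n_y_specific=6, n_silent_xy_shared=2,
    autosome_lengths=(20_000_000,), x_length=8_000_000,
    y_length=4_000_000, par_length=1_600_000,
    rho=0.7,            # X-specific expression in XY males vs XX females
    kappa=0.5,          # X share of gametologue-pair output in XY males
    library_size=2_000_000,
    seed=7,
)

genes, features, layout = dc.generate_annotation(cfg)
counts, samples = dc.generate_counts(genes, cfg)
tracks = dc.generate_depth(cfg, layout)

print("gene classes:")
print(genes["region"].value_counts().to_string())
print("\nsamples:")
print(samples.to_string(index=False))
print("\ncount matrix:", counts.shape, "- first rows:")
print(counts.head(3).to_string())

outdir = Path("example_fixtures")
paths = dc.write_fixtures(genes, features, counts, samples, tracks,
                          layout, outdir)
print("\nwrote:", ", ".join(p for p in sorted(paths.values())))
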