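"""Find the pseudoautosomal boundary from DNA read depth.

Over the PAR both sexes carry two copies, so male depth matches the
autosomal level; over X-specific sequence an XY male is hemizygous and
depth halves. A single-changepoint fit on the windowed depth ratio
locates where that halving starts.
"""

import dosagecomp as dc
from dosagecomp import regions

cfg = dc.SimulationConfig(seed=3)  # full-size genome, 20 kb windows
tracks = dc.generate_depth(cfg)

ratio_tracks, auto_median = regions.normalize_depth(
    tracks, list(cfg.layout().autosomes))
print(f"autosomal median depth: {auto_median:.1f}x")

for scaffold, track in ratio_tracks.items():
    call = regions.call_scaffold_class(track)
    print(f"{scaffold}: {call.call:15s} median ratio {call.median_ratio:.3f}")

boundary = regions.detect_par_boundary(ratio_tracks[cfg.layout().x_scaffold])
print(f"\nPAR boundary on {boundary.scaffold}: {boundary.boundary_bp:,} bp "
      f"(truth: {cfg.par_length:,})")
print(f"diploid-side mean ratio {boundary.diploid_mean:.3f}, "
      f"hemizygous-side {boundary.hemizygous_mean:.3f}, "
      f"SSE reduction {boundary.sse_reduction:.1%}")
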