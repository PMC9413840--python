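"""Run the whole chain end-to-end on a reduced synthetic cohort.

simulate -> FD/censoring/retention -> 36P nuisance regression -> ALFF ->
band-pass + connectivity + MST metrics -> permutation/FDR statistics and
the motion-sensitivity suite, written to a reproducible run directory.
"""

import tempfile
from pathlib import Path

from mstconnect import CohortSpec, RunConfig, run_pipeline

cfg = RunConfig(
    cohort=CohortSpec(n_group_a=24, n_group_b=22, n_rois=60, n_volumes=200, seed=5),
    n_perm=2000,
    seed=5,
    exclusion="none",
)

with tempfile.TemporaryDirectory() as tmp:
    result = run_pipeline(cfg, outdir=Path(tmp) / "run")
    r = result.report
    print(f"subjects analyzed: {r['n_analyzed']} / {r['n_subjects']}"
          f" (excluded by retention rule: {r['n_excluded']})")
    print(f"motion omnibus p (group / interaction): "
          f"{r['motion_omnibus']['p_group']:.4f} / {r['motion_omnibus']['p_interaction']:.4f}")
    print(f"global network omnibus p (group): {r['global_omnibus']['p_group']:.4f}")
    print(f"leaf fraction excluded as motion-confounded: {r['leaf_fraction_excluded']}")
    print(f"FDR-significant nodes (betweenness): {r['n_significant_nodes_bc']}")
    print(f"FDR-significant ROIs (ALFF): {r['n_significant_rois_alff']}")
    print(f"edges correlated with mean FD after FDR: {r['pct_edges_fd_correlated']:.1f}%")
    print(f"run directory files: {sorted(p.name for p in (Path(tmp) / 'run').iterdir())}")
# The planted conditions (group A moves less; its connectivity tree has
# three hubs) surface as a significant motion group effect and a set of
# FDR-significant betweenness nodes, while the run log pins every seed
# and threshold for bit-identical reruns.
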