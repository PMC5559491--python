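"""Rigid vs flexible inclusions: rupture strain and peak interaction stress.

Matched membrane patches share the same cohesive detach length; only the
inclusion differs — rigid (no compliance, no conformational fluctuation)
or flexible (compliance 0.65 plus thermal conformational jitter).  The
rigid complex concentrates the interface loading, so it ruptures at a
smaller applied strain and a higher peak interaction stress.
"""

import numpy as np

from mdmech.fixtures import make_mock_membrane_stretch
from mdmech.groups import AtomGroup, GroupSpec
from mdmech.pipeline import extract_series
from mdmech.rupture import detect_rupture, summarize_runs

spec = GroupSpec(name="x", rule="explicit", atom_ids=(1,))
summaries = []
for variant in ("rigid", "flexible"):
    run = make_mock_membrane_stretch(seed=3, variant=variant,
                                     failure_mode="length",
                                     detach_length=2.5)
    inclusion = AtomGroup("INC", run.inclusion_ids, spec, 0)
    lipids = AtomGroup("LIP", run.lipid_ids, spec, 0)
    result = extract_series(run.frames, run.topo, run.params,
                            inner=inclusion, outer=lipids,
                            system=variant, rate_label=1e7, progress_every=0)
    summary = detect_rupture(result.stress_strain_curve())
    summaries.append(summary)
    print(f"{variant:9s} rupture strain {summary.rupture_strain:.3f}, "
          f"peak stress {summary.rupture_stress_mpa:7.1f} MPa")

table = summarize_runs(summaries)
print(table[["system", "rupture_strain", "rupture_stress_mpa",
             "rupture_tension_mn_per_m"]].to_string(index=False))
# The rigid row should show the smaller strain and larger stress: the
# compliant inclusion absorbs part of the applied stretch, so its
# interface bonds load more slowly, and its conformational fluctuations
# break them slightly below the deterministic detach elongation.
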