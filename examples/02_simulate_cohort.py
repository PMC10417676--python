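"""Generate a synthetic 30-patient cohort and summarize its IRS scores.

The default configuration reproduces the reference cohort composition
(3/20/6/1 CR/PR/SD/PD), one ~100-worm plate per urine sample, and latent
class trajectories calibrated so the noise-free per-class IRS3 medians are
CR 0.103, PR 0.033, SD -0.027.
"""

from collections import Counter

from nnose import Response, SimulationConfig, median_iqr, simulate_cohort
from nnose.chemotaxis import ci_table
from nnose.irs import irs_table

cfg = SimulationConfig(seed=1)
patients, plates = simulate_cohort(cfg)
print("response classes:", dict(Counter(p.response.value for p in patients)))
print(f"plates: {len(plates)} ({cfg.n_worms_per_plate} worms each)\n")

records = irs_table(ci_table(plates), cohort=patients)
cls_of = {p.patient_id: p.response for p in patients}

for label, classes in [
    ("CR", {Response.CR}),
    ("CR or PR", {Response.CR, Response.PR}),
    ("SD or PD", {Response.SD, Response.PD}),
]:
    vals = [r.irs3 for r in records if cls_of[r.patient_id] in classes]
    med, q1, q3 = median_iqr(vals)
    print(f"IRS3 {label:9s} (n={len(vals):2d}): "
          f"median {med:+.3f}  [IQR {q1:+.3f}, {q3:+.3f}]")

print("\nResponders' indices fall over therapy (positive IRS3); plate-level")
print("counting noise at 100 worms/plate widens the spread well beyond the")
print("latent class separation.")
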