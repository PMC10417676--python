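"""Chemotaxis indices and index reduction scores for one patient.

Builds plate counts for three urine samples (pre-treatment, pre-surgery,
post-surgery), computes the per-plate chemotaxis index, aggregates
replicates, and derives the three index reduction scores.
"""

from nnose import PlateAssay, Timepoint, aggregate_ci, chemotaxis_index, compute_irs

T1, T2, T3 = Timepoint

# two replicate plates per timepoint, ~100 worms each
plates = {
    T1: [PlateAssay("pt-01", T1, "t1-a", 55, 20, 25),
         PlateAssay("pt-01", T1, "t1-b", 49, 26, 25)],
    T2: [PlateAssay("pt-01", T2, "t2-a", 46, 31, 23),
         PlateAssay("pt-01", T2, "t2-b", 40, 30, 30)],
    T3: [PlateAssay("pt-01", T3, "t3-a", 38, 37, 25),
         PlateAssay("pt-01", T3, "t3-b", 33, 36, 31)],
}

for tp, group in plates.items():
    per_plate = ", ".join(f"{chemotaxis_index(p):+.3f}" for p in group)
    sample = aggregate_ci(group)
    print(f"{tp.value}: plate CIs [{per_plate}]  ->  sample CI {sample.ci:+.3f}")

cis = {tp: aggregate_ci(group).ci for tp, group in plates.items()}
irs = compute_irs(cis[T1], cis[T2], cis[T3], patient_id="pt-01")
print(f"\nIRS1 (T1-T2) = {irs.irs1:+.3f}   chemotherapy-interval decline")
print(f"IRS2 (T2-T3) = {irs.irs2:+.3f}   surgery-interval decline")
print(f"IRS3 (T1-T3) = {irs.irs3:+.3f}   overall decline (= IRS1 + IRS2)")
print("\nPositive scores mean the worms' attraction to the patient's urine")
print("fell over the interval — the expected direction under effective therapy.")
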