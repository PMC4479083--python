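"""Simulate a serial-biopsy cohort and look at its design.

Draws the default synthetic cohort: 48 patients biopsied before treatment
(T1), 24-96 h after the first chemotherapy dose (T2, 25 % missing) and at
surgery (TS, patients with residual disease only), with planted
proliferation/immune downshifts at T2, response-linked early changes and
recurrence hazards in the residual tumor.
"""

from serialdex import SimConfig, simulate_cohort

expr, meta, truth = simulate_cohort(SimConfig(seed=1))

print(f"expression matrix: {expr.shape[0]} genes x {expr.shape[1]} samples")
print("samples per time point:", meta["timepoint"].value_counts().to_dict())
print("RCB groups (patients):",
      meta.drop_duplicates("patient_id")["rcb_group"].value_counts().to_dict())
print(f"planted: {len(truth.prolif_genes)} proliferation, {len(truth.immune_genes)} immune, "
      f"{len(truth.response_genes)} response, {len(truth.hazard_genes)} hazard genes")
# The T1/T2/TS counts mirror a serial neoadjuvant design with incomplete
# pairing; the truth record drives sensitivity/FDR evaluation downstream.
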