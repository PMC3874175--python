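"""Energy-matrix motif scanning and conserved predicted interactions.

A PWM becomes a binding energy matrix (0 kT at the consensus base per
position); window occupancy is 1/(1 + exp(E - mu)) and sites are called
at occupancy >= 0.09, i.e. E <= ln(1/0.09 - 1) ~= 2.31 kT.
"""

import numpy as np

from intronreg.motifscan import (
    PWM,
    conserved_predicted_tfs,
    pwm_to_energy,
    scan_fragment,
)

mat = np.full((6, 4), 0.05)
for i, b in enumerate("ACGTAC"):
    mat[i, "ACGT".index(b)] = 0.85
em = pwm_to_energy(PWM(tf_id="tfA", matrix=mat))
print(f"energy cutoff for occupancy 0.09: {em.energy_cutoff:.4f} kT")

seq = "TTTTT" + "ACGTAC" + "TTTTTTTTTT" + "GTACGT" + "TTTTT"
for site in scan_fragment(seq, em):
    print(f"site at offset {site.offset} ({site.strand}): "
          f"E = {site.energy:.3f} kT, occupancy = {site.occupancy:.3f}")

frag_a = "GGGGG" + "ACGTAC" + "GGGGG"   # site in species A
frag_b = "CCCCC" + "ACGTAC" + "CCCCC"   # site in species B ortholog
print("conserved TFs (predicted in both orthologous fragments):",
      conserved_predicted_tfs(frag_a, frag_b, [em]))
print("\nThe planted consensus scores E = 0 (occupancy 0.5); its reverse "
      "complement is found on the minus strand.  A TF predicted in both "
      "species' fragments counts as a conserved predicted interaction.")
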