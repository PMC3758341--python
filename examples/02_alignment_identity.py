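"""Global alignment and the percent-identity divergence measure.

Percent identity is 2 * n_id / (n_a + n_b): identical aligned residue
pairs over the average of the two unaligned lengths.  High identity
means low protein divergence.
"""

from imco import ProteinSequence, ScoringScheme, global_align, percent_identity

a = ProteinSequence("human_gene", "MKTLVWAACDEFGHIKLMNP")
b = ProteinSequence("mouse_gene", "MKTLVWSACDEFGHKLMNP")  # 1 sub + 1 deletion

result = global_align(a, b, ScoringScheme())  # BLOSUM62, gap 10/0.5
print("aligned:")
print(" ", result.aligned_a)
print(" ", result.aligned_b)
print(f"identical pairs n_id = {result.n_id}, lengths = {result.len_a}, {result.len_b}")
print(f"percent identity psi = {percent_identity(result):.2f}%")
# psi close to 100 -> nearly undiverged proteins; each substitution or
# indel pulls it down.
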