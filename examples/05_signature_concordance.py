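"""Direction concordance between a DE profile and resistance signatures.

A drug-resistance signature lists genes with expected directions.  Under
the null each evaluable gene matches with probability 1/2, so the number of
concordant genes is Binomial(n, 1/2); the one-sided upper tail scores the
evidence that the profile looks resistant.
"""

from stemdis import ResistanceSignature, concordance_test
from stemdis.de import DEResult
from stemdis.synthetic import gen_signature

for fraction in (1.0, 0.9, 0.5):
    entries, truth = gen_signature(30, concordant_fraction=fraction, seed=2)
    de_table = [
        DEResult(gene=row.entity_id, log2fc=row.planted_effect, p=0.001,
                 q=0.001, label="up" if row.planted_effect > 0 else "down")
        for row in truth.itertuples()
    ]
    sig = ResistanceSignature(f"sim_{fraction}", tuple(entries))
    res = concordance_test(sig, de_table)
    print(f"concordant fraction {fraction:.1f}: {res.n_concordant}/"
          f"{res.n_evaluable} concordant, p = {res.p:.3e}")

print()
print("At fraction 1.0 the p-value is the closed form 0.5^30 = 9.3e-10; at")
print("0.5 the profile is unrelated to the signature and p is unremarkable.")
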