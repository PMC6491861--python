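"""Held-out classification of remote relationships, desk scale.

Simulates training and test reference sets of third-degree to unrelated
pairs (30 pairs per class, 8,000 SNPs at MAF 0.5), fits log-ratio PCA on the
training compositions, projects the test pairs and classifies them with LDA
on three principal components.
"""

from lrkin import classification_experiment

res = classification_experiment(
    maf=0.5,
    n_snps=8_000,
    relationships=("FC", "4th", "5th", "6th", "UN"),
    n_pairs=30,
    d_values=(1, 3, 5),
    seed=42,
)

for d, rate in res.overall_rates.items():
    print(f"{d} principal component(s): overall held-out rate {100 * rate:.1f}%")
print("\nper-class rates with 3 PCs:")
print((100 * res.class_rates[3]).round(1).to_string())
print("\nconfusion matrix (rows = truth, columns = prediction), 3 PCs:")
print(res.confusions[3])
# Third degree is recovered perfectly and fourth degree nearly so; errors
# concentrate where fifth- and sixth-degree pairs blur into the unrelated
# cloud.  At the full study scale (35,000 SNPs, 100 pairs per class) the
# overall rate reaches ~95%.
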