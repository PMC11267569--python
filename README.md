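# fcgrcaps

Two-stage identification of transcriptional enhancers from DNA sequence,
using chaos-game sequence images and a capsule network.

Enhancers are short noncoding DNA elements that amplify transcription of
their target genes. Locating them experimentally (e.g. by ChIP-seq) is slow
and expensive, so sequence-based classifiers are widely used: given a 200 bp
genomic fragment, decide (stage 1) whether it is an enhancer at all and, if
so, (stage 2) whether it is a strong or a weak one. `fcgrcaps` is a complete,
CPU-friendly implementation of the image-based approach to this problem, for
computational biologists who want a reproducible, inspectable pipeline with
scikit-learn-style estimators.

## Method

**Encoding.** The chaos game representation (CGR) assigns the nucleotides to
the corners of the square [−1, 1]² (A upper-left, C lower-left, G
lower-right, T upper-right) and maps a sequence s = s₁…sₙ to points

&nbsp;&nbsp;&nbsp;&nbsp;(xᵢ, yᵢ) = ½ ((xᵢ₋₁, yᵢ₋₁) + corner(sᵢ)), (x₀, y₀) = (0, 0).

All points whose generating subsequence ends with the same length-k suffix
fall in the same dyadic sub-square, so counting points on an N×N grid with
N = 2ᵏ yields exactly the k-mer frequency table — the *frequency* CGR
(FCGR). We use N = 64 (6-mer resolution) by default. This equivalence is not
assumed but proven at runtime against a brute-force sliding-window k-mer
counter, cell for cell.

**Classifier.** Each FCGR image passes through a small convolutional
frontend, then a primary capsule layer: L activity vectors uᵢ ∈ ℝᵐ squashed
by v = (‖s‖²/(1+‖s‖²)) s/‖s‖ so their lengths read as probabilities.
Prediction vectors û_{j|i} = W_{i,j} uᵢ are routed to J = 2 type capsules
Vⱼ ∈ ℝⁿ by dynamic routing: coupling coefficients c_{i,j} = softmax_j(b_{i,j})
weight the sum Sⱼ = Σᵢ c_{i,j} û_{j|i}, Vⱼ = squash(Sⱼ), and the logits are
sharpened by the agreement b_{i,j} += û_{j|i}·Vⱼ for r iterations. The class
scores are the capsule lengths pⱼ = ‖Vⱼ‖; training minimizes the margin loss
Σⱼ Tⱼ max(0, m⁺−pⱼ)² + λ(1−Tⱼ) max(0, pⱼ−m⁻)² with Adam. The whole network —
forward pass, unrolled-routing gradients, optimizer — is implemented in
NumPy and verified against finite differences and an independent
straight-line reference in the test suite.

Both stages share one FCGR representation; a dense-head ablation model
(`DenseHeadClassifier`) swaps the capsule layers for an MLP while keeping
the identical pipeline, for architecture comparisons. Evaluation reports
accuracy, sensitivity, specificity, the Matthews correlation coefficient and
the Mann–Whitney AUC; metrics with zero denominators are reported as null,
never as 0.

Because real benchmark data need not be downloaded to develop or test
anything, the `simdata` module generates benchmark-shaped synthetic data:
fixed-length sequences whose classes differ in GC content (enhancer-like
classes GC-richer, strong > weak > nonenhancer) with optional planted k-mer
motifs, all reproducible from a manifest.

## Worked example

```python
import numpy as np
from fcgrcaps import (ClassProfile, CapsNetClassifier, FCGREncoder,
                      cgr_encode, encode_sequence, generate_class, evaluate)

cgr_encode("CATG")
# array([[-0.5   , -0.5   ],
#        [-0.75  ,  0.25  ],
#        [ 0.125 ,  0.625 ],
#        [ 0.5625, -0.1875]])
encode_sequence("ACGTACGT", resolution=4).counts   # 2-mer table as an image
# array([[0, 1, 0, 0],
#        [0, 1, 0, 2],
#        [2, 0, 0, 0],
#        [0, 0, 2, 0]])

rng = np.random.default_rng(7)
enh = ClassProfile("enhancer", gc_fraction=0.60)
non = ClassProfile("nonenhancer", gc_fraction=0.40)
train = generate_class(100, enh, rng, "tr_e") + generate_class(100, non, rng, "tr_n")
test  = generate_class(50, enh, rng, "te_e") + generate_class(50, non, rng, "te_n")
enc = FCGREncoder(resolution=64)
Xtr, ytr = enc.transform(train), np.array([r.label for r in train])
Xte, yte = enc.transform(test),  np.array([r.label for r in test])

clf = CapsNetClassifier(n_epochs=15, learning_rate=1e-3, random_state=7,
                        positive_label="enhancer")
clf.fit(Xtr, ytr)
rep = evaluate(clf, Xte, yte)
print(f"ACC {rep.accuracy:.1f}%  SN {rep.sensitivity:.1f}%  "
      f"SP {rep.specificity:.1f}%  MCC {rep.mcc:.3f}  AUC {rep.auc:.1f}%")
# ACC 99.0%  SN 100.0%  SP 98.0%  MCC 0.980  AUC 99.4%
```

The first block shows the midpoint trajectory of `CATG` and that at N = 4
the FCGR of `ACGTACGT` is its 2-mer count table (AC and CG twice, GT twice,
TA once; the first point predates any full 2-mer). The second block trains
the capsule classifier on a synthetic GC-contrast dataset and evaluates on a
held-out split: the 0.40-vs-0.60 GC gap is nearly perfectly recoverable.

The same workflow is available from the shell:

```
fcgrcaps simulate --preset benchmark-like --scale 0.1 --seed 7 --out data/
fcgrcaps train --fasta data/stage1.fasta --labels data/stage1.labels.tsv \
               --epochs 30 --seed 7 --out stage1.npz
fcgrcaps evaluate --model stage1.npz --fasta data/test.fasta \
                  --labels data/test.labels.tsv --out metrics.json
```

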