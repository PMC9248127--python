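# ocsrkit

Optical chemical structure recognition (OCSR) turns a raster depiction of a
molecule — the kind printed in journal articles and patents — back into a
machine-readable structure string. `ocsrkit` is an end-to-end toolkit for
building and studying such a recognizer:

1. **Corpus generation.** From a list of source SMILES it builds a
   four-category synthetic corpus — Kekulé vs. aromatic ring forms, each
   with and without randomly attached patent-style substituents and bracket
   atoms — converts every molecule to
   [DeepSMILES](https://doi.org/10.26434/chemrxiv.7097960.v1) (a SMILES
   dialect in which ring-closure digit pairs become a single ring-size
   digit and paired parentheses become runs of `)`), and splits each
   category 18:1:1 into train/validation/test.
2. **Depiction.** Molecules are rendered as 2D line diagrams (RDKit),
   thresholded to a binary ink mask, padded, resized with nearest-neighbour
   interpolation and replicated to three identical channels.
3. **Recognition model.** A hierarchical window-attention backbone (4×4
   patch embedding; alternating window / shifted-window multi-head
   self-attention; patch merging between the four stages) flattens the
   final feature map into a sequence *S*<sub>b</sub> — 49 positions × 1536
   channels for a 224×224 input at embedding width 192.  A stack of six
   standard transformer encoder layers produces *S*<sub>e</sub>, and six
   masked decoder layers with cross-attention over *S*<sub>e</sub> emit
   DeepSMILES tokens autoregressively.  The whole network runs on a compact
   NumPy reverse-mode autodiff engine included in the package
   (`ocsrkit.nn`), so there is no deep-learning-framework dependency.
4. **Objectives.** Standard softmax cross-entropy, or a **multi-label focal
   loss** for the long-tailed token distribution of DeepSMILES corpora:
   each class logit *o*<sub>i</sub> is squashed by a sigmoid,
   *p*<sub>i</sub> = σ(*o*<sub>i</sub>) if *y*<sub>i</sub> = 1 else
   1 − σ(*o*<sub>i</sub>), and

   MFL = (1/n) Σ<sub>i</sub> −α<sub>i</sub> (1 − p<sub>i</sub>)<sup>γ</sup> log p<sub>i</sub>

   with per-class weights α<sub>i</sub> and focusing parameter γ.
5. **Evaluation.** Exact-match accuracy, fingerprint Tanimoto (invalid
   predictions score 0), corpus BLEU-4, ROUGE-L F1, the two validity rates
   (parseable DeepSMILES / decodable to a valid molecule), stratified by
   corpus category and by reference-length bin
   ([1,25], [26,50], [51,75], [76,100]).

## Worked example

Desk-scale end-to-end run (generated corpus → rendered depictions → tiny
model memorizes its own training set → full evaluation report):

```python
import numpy as np
from ocsrkit import (
    generate_tiny_corpus, Vocabulary, DepictionStyle, render_dataset,
    ModelConfig, OCSRModel, TrainConfig, train, predict_deepsmiles,
    stratified_report,
)

records = generate_tiny_corpus(6, seed=1)          # 24 molecules, 4 categories
vocab = Vocabulary.from_corpus([r.deepsmiles for r in records])
max_len = max(len(r.deepsmiles) for r in records) + 2
style = DepictionStyle(canvas=64, bond_line_width=2.0,
                       min_font_size=6, max_font_size=10, rotation_jitter=0.0)
samples, _ = render_dataset(records, vocab, max_len, style=style,
                            seed=0, image_size=64)

model = OCSRModel(ModelConfig.tiny(vocab.size, image_size=64,
                                   max_len=max_len), seed=0)
cfg = TrainConfig(epochs=400, batch_size=24, lr=1e-3, seed=0,
                  step_size=200, warmup_epochs=20)
train(model, samples, vocab, cfg, log=None)

preds = predict_deepsmiles(model, np.stack([s.image for s in samples]), vocab)
report = stratified_report(preds, [s.record.deepsmiles for s in samples],
                           [s.record for s in samples])
print(report.summary())
```

prints (five to ten minutes on one CPU core):

```
evaluated            24
accuracy             1.0000
tanimoto             1.0000
BLEU                 1.0000
ROUGE-L              1.0000
valid DeepSMILES     1.0000
valid SMILES         1.0000
category 1 accuracy  1.0000  (n=6)
category 2 accuracy  1.0000  (n=6)
category 3 accuracy  1.0000  (n=6)
category 4 accuracy  1.0000  (n=6)
length [1,25]    acc  1.0000  (n=16)
length [26,50]   acc  1.0000  (n=8)
```

Accuracy 1.0 means every one of the 24 depictions was decoded to its exact
DeepSMILES label, character for character; the Tanimoto/BLEU/ROUGE values
of 1.0 follow necessarily, and the validity rates confirm that every
prediction parsed as DeepSMILES and decoded to a valid molecule.

The same pipeline is scriptable from the shell:

```bash
ocsrkit generate --n-per-category 8 --seed 1 --out corpus/
ocsrkit render --manifest corpus/manifest.tsv --out imgs/ --image-size 64 --canvas 64
ocsrkit train --images imgs/ --out run/ --seed 0
ocsrkit evaluate --checkpoint run/checkpoint.npz --vocab run/vocab.txt --images imgs/
ocsrkit predict --checkpoint run/checkpoint.npz --vocab run/vocab.txt imgs/mol_000000.png
```

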