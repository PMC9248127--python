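# Methods

## Problem and model

The toolkit treats optical chemical structure recognition as image-to-
sequence translation.  The target representation is DeepSMILES with both
rewrites active: branches are closed by runs of `)` (each `)` pops one atom
off the depth-first traversal stack) and ring closures are a single digit
giving the distance back along that stack (`%NN` for 10–99).  DeepSMILES
removes the two pairing constraints (matched parentheses, matched ring
digits) that autoregressive decoders most often violate, so more raw
predictions parse.  Because SMILES is written depth-first, every ring bond
points to an ancestor on the stack; hand-written SMILES violating this
(cross-branch closures) are rejected rather than silently mis-encoded.

The network is the standard three-part arrangement:

* **Backbone** — a four-stage hierarchical window-attention encoder.  The
  image is cut into 4×4 patches and embedded (width 192 at full scale);
  each stage alternates attention within fixed 7×7 windows and within
  windows shifted by half a window (cyclic shift + boundary mask), with a
  learned relative-position bias per head; between stages 2×2 patch
  neighbourhoods are concatenated and projected, halving resolution and
  doubling channels.  The final map is flattened to the sequence
  *S*<sub>b</sub>; for 224×224 input that is (224/4/2³)² = 49 positions ×
  192·2³ = 1536 channels.
* **Encoder** — a learned linear map takes *S*<sub>b</sub> to the text
  width *d*=256, a fixed sinusoidal positional encoding is added, and six
  standard layers (self-attention + MLP, each sublayer followed by residual
  and layer norm) produce *S*<sub>e</sub>.
* **Decoder** — six layers of masked self-attention, cross-attention over
  *S*<sub>e</sub>, and MLP, same residual/norm arrangement, then a linear
  head over the vocabulary.  The causal mask makes the logits at position
  *i* a function of tokens < *i* only; this is property-tested for 1- and
  2-layer decoders.  Greedy decoding takes the arg-max at each step
  (lowest id on ties, via `np.argmax`) until the end marker or the length
  cap.  Beam search is out of scope.

The stage depths (2,2,18,2) and heads (6,12,24,48) follow the large-model
convention that accompanies embedding width 192; the projection from 1536
to 256 channels is a learned linear map; sinusoidal (not learned)
positional encodings are used on both text-side stacks.  The backbone sits
behind the *S*<sub>b</sub> contract, so a CNN could be slotted in, but none
is implemented.

### Why NumPy

The network, including its training loop, runs on a small reverse-mode
autodiff engine (`ocsrkit.nn.autodiff`) written on NumPy.  Softmax, layer
norm, attention and both losses are *composed* from ~20 primitives, each
covered by a numerical-vs-analytic gradient check (tolerance 1e-4
relative, float64), so the whole model is differentiated by verified
parts.  This keeps the package dependency-light and makes every numeric
step inspectable; the cost is speed, which the desk-scale configuration
(below) is sized for.

## Synthetic corpus

The generator emulates the composition of large OCSR training sets built
from public compound libraries: four categories crossing ring form
(Kekulé / aromatic) with substituent decoration (without / with).
Decoration is realized as graph-level attachment: 1–3 fragments, drawn
uniformly from a pool of 32 patent-style substituents (halogens, CF₃,
nitro, methoxy, sulfonamide, phenyl, morpholino, …) plus the 17 bracket
atoms ([Pb], [NH], [Ru], [Li], [K], [Si], [S+], [O], [O-], [N+], [N],
[P], [C], [H], [2H], [3H], [B]), are bonded to uniformly chosen atoms
that still carry a hydrogen.  Graph-level attachment guarantees a valid
molecule, unlike splicing substituent text into the SMILES string;
attachments that fail sanitization are retried at another draw, with
rejection after a bounded number of attempts.  The substituent pool is a
plain-text file and can be swapped for a larger inventory.  Deduplication
is by canonical SMILES within each category.  Splits are 18:1:1 per
category, with integer remainders assigned to the training split (the
choice only matters for small corpora; at 1.25 M per category the division
is exact: 1,125,000 / 62,500 / 62,500).

Rendering uses RDKit's 2D depictor with a style layer (fonts, bond width,
label padding, rotation jitter, optional condensed-formula abbreviations
via RDKit's abbreviation facility).  Parity with any particular Java
depiction engine is not attempted; the style layer only approximates
literature conventions.  Depictions are thresholded at 0.5 of the
intensity range (configurable; ink = 1, background = 0), padded to a
square with background, resized with nearest-neighbour interpolation
(which provably preserves the {0,1} value set), and replicated to three
identical channels.

What the generator does **not** emulate: scanned-page noise, low
resolution, wavy bonds, superatom abbreviations drawn by other software,
or the style diversity of real literature.  Tests passing on this corpus
therefore demonstrate that the architecture, losses and pipeline are
correct and learnable — not that the model generalizes to real published
figures, which is known to require far broader training styles.

## Vocabulary and losses

Tokens are single characters; the bundled reference inventory has the 76
characters observed across a multi-million-molecule DeepSMILES corpus,
plus start/end/pad markers appended after the character ids.  Corpus-built
vocabularies are sorted for reproducibility and are always a subset of the
reference inventory.  `max_len` defaults to 150, covering observed label
lengths (bins up to 100) with margin.

Focal-loss defaults follow the object-detection convention: γ = 2,
α<sub>i</sub> = 0.25 uniform.  An inverse-frequency α (∝ 1/(count +
smoothing), normalized to mean 1) is available, fed by the token-frequency
table.  Pad positions are masked from both losses; the class average is
fixed by the MFL definition and the position reduction is the mean over
unmasked positions.  The multi-label cast keeps the full vocabulary,
specials included, as classes.

## Training

Adam, initial learning rate 5e-4 (full scale; 1e-3 at desk scale), batch
256 at full scale.  Two parameter groups: the backbone follows a cosine
decay over the run; the transformer (projection + encoder + decoder)
follows a step decay, ×0.5 every 10 epochs by default.  An optional linear
warmup (applied to both groups) stabilizes the post-norm transformer early
in training — without it, small-data runs can stall in a local optimum
where the decoder ignores the image and behaves as a pure language model.
Gradients are clipped to global norm 1.  Checkpoint selection uses
validation exact-match accuracy.

## Desk-scale configuration

All tests and the acceptance script run a reduced problem sized for a
single CPU core:

* 24 molecules (6 per category) from the bundled 56-molecule list;
  DeepSMILES labels 7–39 characters.
* 64×64 images rendered directly at canvas 64 with bond width 2.  Rendering
  at a large canvas and downsampling is *not* used for training inputs:
  nearest-neighbour decimation of thin lines destroys most ink (measured
  ink fraction drops from ~5% to ~1%), making depictions nearly
  indistinguishable.
* `ModelConfig.tiny()`: embedding 48, depths (2,2,2,2), heads (2,4,8,16),
  window 4, *d*=128, 2 encoder + 2 decoder layers, 4 heads, dropout 0 —
  4.3 M parameters.
* 400 full-batch epochs, lr 1e-3, warmup 20 epochs, step decay at 200.

Under this configuration the model memorizes its 24 training fixtures to
100% exact match in five to ten minutes (≥ 95% across the seeds tried), the
desk-scale surrogate for large-scale learnability: the architecture can
bind depiction features to exact token sequences through the
backbone–encoder–decoder path.

## Numerical and design notes

* Ink polarity is ink = 1 internally; PNG export is black-on-white.
* Binarization is strict `intensity < t·255`, so raising `t` never removes
  ink (monotonicity is property-tested).
* BLEU is corpus-level up to 4-grams with brevity penalty; n-gram orders
  with no candidates anywhere in the corpus (all references shorter than
  n) are dropped from the geometric mean, so identical short corpora score
  1 rather than 0.  ROUGE-L is the mean per-pair F1 over character tokens.
* Tanimoto uses RDKit's deterministic path-based fingerprint (2048 bits)
  by default; the scheme is configurable ("morgan" available) and recorded
  in the report.  Parity with any specific external fingerprint is not
  claimed; an independent bit-set computation cross-checks the division.
* Reference-length bins are inclusive: [1,25], [26,50], [51,75], [76,100],
  with an overflow bin so stratum counts always sum to the total.
* Greedy decoding is deterministic in eval mode; dropout is the only
  stochastic layer and draws from the model's seeded generator.
* Degenerate inputs: blank depictions are flagged and excluded with a
  reason; molecules with no substitutable hydrogen are rejected by the
  decorator; categories with fewer than 20 records split degenerately
  (remainders to train) with a warning.

## Known limitations

* No pretrained backbone weights, mixed precision, or distributed
  training; full-scale (millions of images) training is far outside the
  NumPy engine's performance envelope.
* Real-world literature images are out of scope end to end.
* The 224-substituent patent inventory is represented by a 32-fragment
  pool; the pool file is swappable.
* DeepSMILES encoding rejects non-depth-first SMILES rather than
  re-canonicalizing them; inputs should come from a standard canonical
  writer (as the corpus generator guarantees).
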