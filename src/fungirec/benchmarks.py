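"""Published benchmark figures for the fungi recognition systems.

Reference accuracies reported for the deployed first-generation service
(an Inception CNN ensemble trained on the FGVCx Fungi'18 data) and its
Vision-Transformer successor trained on the Danish Fungi 2020 (DF20)
collection. They are inputs to the consistency checks in
``scripts/acceptance.py`` — headline "error lowered by X%" claims are
plain arithmetic over these numbers, recomputed here via
:func:`fungirec.evaluation.relative_error_reduction`.
"""

from __future__ import annotations

# -- FGVCx Fungi'18 validation set: single best CNN, one central crop ------
#    top-1 before / after re-expressing posteriors under the (uniform)
#    validation-set prior.
FUNGI18_SINGLE_CNN_TOP1_BASELINE = 48.8
FUNGI18_SINGLE_CNN_TOP1_PRIOR_ADJUSTED = 52.6

# -- DF20 test set, 384x384 inputs ----------------------------------------
#    best image-only top-1 (ViT-Large/16) and the top-1 gain from fusing
#    habitat + month + substrate metadata into its posteriors.
DF20_VIT_LARGE_384_TOP1 = 80.45
DF20_VIT_LARGE_384_METADATA_TOP1_GAIN = 2.95

# -- 2021 hold-out observations (DF21): deployed system vs successor ------
#    first-generation CNN (no metadata) vs ViT-Large/16 trained on DF20
#    with metadata fusion.
DF21_FIRST_GENERATION_TOP1 = 69.28
DF21_VIT_LARGE_METADATA_TOP1 = 83.64

# -- FGVCx Fungi'18 private test set, top-3 -------------------------------
FUNGI18_PRIVATE_TOP3_FIRST_GENERATION = 70.69
FUNGI18_PRIVATE_TOP3_VIT_LARGE = 77.28
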