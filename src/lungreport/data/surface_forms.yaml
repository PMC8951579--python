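# English surface forms used when filling report template slots.
# Keys are the canonical label spellings of the vocabulary.
location:
  RUL: "right upper lobe (RUL)"
  RML: "right middle lobe (RML)"
  RLL: "right lower lobe (RLL)"
  LUL: "left upper lobe (LUL)"
  LLL: "left lower lobe (LLL)"
  Lingular Lobe: "lingular lobe"
texture:
  Solid: "solid"
  Subsolid: "subsolid"
  Pure GGO: "pure ground-glass"
margin:
  Sharp Circumscribed: "sharp circumscribed"
  Lobulated: "lobulated"
  Indistinct: "indistinct"
  Spiculated: "spiculated"
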