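# Default Lung-RADS rule table.
#
# Branch structure: texture decides the path; margin refines it only for
# subsolid nodules (benign-leaning sharp/lobulated margins vs. suspicious
# spiculated/indistinct margins); size (mm, half-open intervals [lo, hi),
# null hi = unbounded) picks the category.  Size cut-offs transcribe the ACR
# Lung-RADS v1.1 baseline thresholds.  Edit or replace this file to track
# revisions of the standard; the engine revalidates totality and determinism
# at load time.
version: "1.1-default"
rules:
  - {texture: [Solid], margin: "*", size: [0, 6], category: "2"}
  - {texture: [Solid], margin: "*", size: [6, 8], category: "3"}
  - {texture: [Solid], margin: "*", size: [8, 15], category: "4A"}
  - {texture: [Solid], margin: "*", size: [15, null], category: "4B"}
  - {texture: [Pure GGO], margin: "*", size: [0, 30], category: "2"}
  - {texture: [Pure GGO], margin: "*", size: [30, null], category: "3"}
  - {texture: [Subsolid], margin: [Sharp Circumscribed, Lobulated], size: [0, 6], category: "2"}
  - {texture: [Subsolid], margin: [Sharp Circumscribed, Lobulated], size: [6, null], category: "3"}
  - {texture: [Subsolid], margin: [Spiculated, Indistinct], size: [0, 8], category: "4A"}
  - {texture: [Subsolid], margin: [Spiculated, Indistinct], size: [8, null], category: "4B"}
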