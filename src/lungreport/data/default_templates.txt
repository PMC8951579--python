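[default]
A {size_mm} {texture} nodule with {margin} margin in the {location}. Lung-RADS {category}.

[narrative]
FINDINGS: There is a single {texture} pulmonary nodule in the {location}, measuring {size_mm}, with {margin} margin.
IMPRESSION: Lung-RADS {category}.

[structured]
Record: {record_id}
Location: {location}
Texture: {texture}
Margin: {margin}
Size: {size_mm}
Lung-RADS: {category}
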