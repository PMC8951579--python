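"""Render a structured radiology report by template slot filling.

Templates are plain text with {slot} placeholders over the five clinical
factors; labels render through an English surface-form lexicon.
"""

from lungreport import (
    LocationLabel,
    LungRADSCategory,
    MarginLabel,
    ReportContext,
    TextureLabel,
    default_templates,
    render_report,
)

context = ReportContext(
    location=LocationLabel.RUL,
    texture=TextureLabel.SOLID,
    margin=MarginLabel.SPICULATED,
    size_mm=16.0,
    category=LungRADSCategory.CAT_4B,
    record_id="case-001",
)
templates = default_templates()
for name in sorted(templates.templates):
    print(f"--- template {name!r} ---")
    print(render_report(context, templates, name))
# Every placeholder is replaced deterministically; the same context always
# produces byte-identical text, which is what a controllable clinical
# reporting pipeline requires.
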