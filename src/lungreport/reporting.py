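"""Structured report rendering by template slot filling.

Report text must be fully controllable in a clinical setting, so rendering
is plain slot substitution: templates are text with ``{slot}`` placeholders
over the five clinical factors (location, texture, margin, size, Lung-RADS
category) plus the record id, and labels are mapped to English surface
forms from a data-file lexicon.  One nodule yields one report; multi-nodule
studies are concatenations upstream.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

from .lungrads import LungRADSCategory
from .schema import LocationLabel, MarginLabel, TextureLabel

__all__ = [
    "ReportContext",
    "TemplateSet",
    "TemplateError",
    "load_templates",
    "default_templates",
    "render_report",
    "report_json",
]

#: placeholders a template may use
KNOWN_SLOTS = frozenset(
    {"location", "texture", "margin", "size_mm", "category", "record_id"}
)


class TemplateError(ValueError):
    """Template file contains an unknown placeholder or is malformed."""


@dataclass(frozen=True)
class ReportContext:
    """Slot values for one nodule's report."""

    location: LocationLabel
    texture: TextureLabel
    margin: MarginLabel
    size_mm: float
    category: LungRADSCategory
    record_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.size_mm > 0:
            raise ValueError(f"size_mm must be positive, got {self.size_mm}")


@dataclass(frozen=True)
class TemplateSet:
    """Named templates; ``default_name`` is used when none is requested."""

    templates: dict[str, str]
    default_name: str = "default"


def _load_surface_forms() -> dict[str, dict[str, str]]:
    ref = resources.files("lungreport.data") / "surface_forms.yaml"
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


_SURFACE_FORMS = _load_surface_forms()


def _placeholders(template: str) -> set[str]:
    try:
        return {name for _, name, _, _ in string.Formatter().parse(template)
                if name is not None}
    except ValueError as exc:
        raise TemplateError(f"malformed placeholder syntax: {exc}") from exc


def _parse_template_file(text: str) -> dict[str, str]:
    """Parse ``[name]`` sections into a name → template-string map."""
    templates: dict[str, str] = {}
    name: Optional[str] = None
    lines: list[str] = []

    def flush() -> None:
        if name is not None:
            templates[name] = "\n".join(lines).strip("\n").strip()

    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("[") and stripped.endswith("]") and len(stripped) > 2:
            flush()
            name = stripped[1:-1]
            lines = []
        elif name is not None:
            lines.append(line)
        elif stripped:
            raise TemplateError(f"content before first [name] header: {stripped!r}")
    flush()
    return {k: v for k, v in templates.items() if v}


def load_templates(path: Union[str, Path]) -> TemplateSet:
    """Load a template file; unknown placeholders are rejected here.

    The file holds one or more ``[name]`` sections whose bodies are template
    strings; the ``default`` section (or the first section) becomes the
    default template.
    """
    text = Path(path).read_text(encoding="utf-8")
    templates = _parse_template_file(text)
    if not templates:
        raise ValueError(f"template file {path} defines no templates")
    for name, template in templates.items():
        unknown = _placeholders(template) - KNOWN_SLOTS
        if unknown:
            raise TemplateError(
                f"template {name!r} uses unknown placeholder(s) "
                f"{sorted(unknown)}; known slots: {sorted(KNOWN_SLOTS)}"
            )
    default_name = "default" if "default" in templates else next(iter(templates))
    return TemplateSet(templates=templates, default_name=default_name)


def default_templates() -> TemplateSet:
    """The shipped template set."""
    ref = resources.files("lungreport.data") / "default_templates.txt"
    with resources.as_file(ref) as path:
        return load_templates(path)


def _surface(kind: str, label) -> str:
    forms = _SURFACE_FORMS[kind]
    try:
        return forms[label.value]
    except KeyError:
        raise ValueError(f"no surface form for {kind} label {label!r}") from None


def render_report(
    context: ReportContext,
    templates: TemplateSet,
    template_name: Optional[str] = None,
) -> str:
    """Fill every slot of the chosen template; deterministic and total.

    Surface forms: lobes render with their abbreviation ("right upper lobe
    (RUL)"), textures and margins in lower case ("pure ground-glass",
    "spiculated"), size to one decimal with unit ("12.0 mm"), and the
    category as printed ("4A").
    """
    name = template_name if template_name is not None else templates.default_name
    try:
        template = templates.templates[name]
    except KeyError:
        raise KeyError(
            f"unknown template {name!r}; available: {sorted(templates.templates)}"
        ) from None
    values = {
        "location": _surface("location", context.location),
        "texture": _surface("texture", context.texture),
        "margin": _surface("margin", context.margin),
        "size_mm": f"{context.size_mm:.1f} mm",
        "category": context.category.value,
        "record_id": context.record_id,
    }
    needed = _placeholders(template)
    missing = [k for k in needed if values.get(k) in (None, "") and k == "record_id"]
    if missing:
        raise ValueError(f"context is missing value(s) for {missing}")
    return template.format(**values)


def report_json(context: ReportContext, text: str) -> str:
    """Machine-readable report: the context values plus the rendered text."""
    payload = {
        "record_id": context.record_id,
        "location": context.location.value,
        "texture": context.texture.value,
        "margin": context.margin.value,
        "size_mm": round(float(context.size_mm), 1),
        "lung_rads": context.category.value,
        "report": text,
        "metadata": context.metadata,
    }
    return json.dumps(payload, indent=2, sort_keys=True)
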