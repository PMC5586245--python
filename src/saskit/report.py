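"""Guideline-structured reporting.

Assembles the outputs of the analysis modules into the four sections the
community publication guidelines ask authors to tabulate -- sample details,
data acquisition, data analysis/validation, and model fitting -- renders them
as readable markdown-like text plus a flat ``key: value`` export, and emits a
completeness checklist listing any mandatory item that is absent.  Absence is
reported, never fatal: the checklist is the product.

Report generation is pure: identical inputs give byte-identical section text
(run provenance such as timestamps lives in a separate footer that the caller
may omit).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

__all__ = ["GuidelineReport", "build_report", "SECTION_ITEMS"]

# mandatory items per section (condensed labels of the guideline tables)
SECTION_ITEMS = {
    "sample": [
        "organism", "source", "sequence_id", "extinction_coefficient",
        "vbar", "contrast", "M_from_composition", "concentration", "solvent",
    ],
    "acquisition": [
        "instrument", "wavelength_A", "q_range_A^-1", "absolute_scaling_method",
        "exposure", "sample_temperature_C",
    ],
    "analysis": [
        "guinier_I0", "guinier_Rg", "guinier_q_range", "guinier_r2",
        "pr_I0", "pr_Rg", "pr_dmax", "pr_q_range", "pr_fit_chi2",
        "porod_volume", "M_from_I0", "M_fischer", "M_vc",
        "kratky_peak", "flexibility_flags", "subtraction_constant",
    ],
    "modelling": [
        "software_versions", "chi2", "scale_c", "constant_adjustment",
        "cormap_p", "residual_plot_reference",
    ],
}


def _fmt(value) -> str:
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


@dataclass
class GuidelineReport:
    sections: dict                 # section -> {item: (value, unit_or_note)}
    missing: dict                  # section -> [absent mandatory items]
    provenance: dict = field(default_factory=dict)

    def render_markdown(self, include_provenance: bool = True) -> str:
        titles = {"sample": "Sample details",
                  "acquisition": "Data acquisition and reduction",
                  "analysis": "Data analysis and validation",
                  "modelling": "Model fitting"}
        out = ["# Small-angle scattering report", ""]
        for sec in ("sample", "acquisition", "analysis", "modelling"):
            out.append(f"## {titles[sec]}")
            items = self.sections.get(sec, {})
            if not items:
                out.append("(no entries)")
            for key, (value, note) in sorted(items.items()):
                suffix = f" [{note}]" if note else ""
                out.append(f"- {key}: {_fmt(value)}{suffix}")
            if self.missing.get(sec):
                out.append(f"- MISSING ITEMS: {', '.join(self.missing[sec])}")
            out.append("")
        out.append("## Completeness checklist")
        total_missing = sum(len(v) for v in self.missing.values())
        out.append(f"- mandatory items absent: {total_missing}")
        for sec, items in self.missing.items():
            for item in items:
                out.append(f"- absent: {sec}.{item}")
        if include_provenance and self.provenance:
            out.append("")
            out.append("## Provenance")
            for key, val in sorted(self.provenance.items()):
                out.append(f"- {key}: {val}")
        return "\n".join(out) + "\n"

    def render_keyvalue(self) -> str:
        lines = []
        for sec in sorted(self.sections):
            for key, (value, note) in sorted(self.sections[sec].items()):
                lines.append(f"{sec}.{key}: {_fmt(value)}")
        for sec, items in sorted(self.missing.items()):
            for item in items:
                lines.append(f"{sec}.{item}: not determined")
        return "\n".join(lines) + "\n"


def build_report(blocks: dict, sample_meta: Optional[dict] = None,
                 provenance: Optional[dict] = None) -> GuidelineReport:
    """Assemble a guideline report.

    ``blocks`` maps section names ("sample", "acquisition", "analysis",
    "modelling") to dicts of item -> value or item -> (value, note).
    ``sample_meta`` is merged into the sample section.  Every mandatory item
    not provided is listed in the completeness checklist with an explicit
    "not determined" in the key-value export.
    """
    sections: dict = {s: {} for s in SECTION_ITEMS}
    merged = dict(blocks)
    if sample_meta:
        merged.setdefault("sample", {})
        merged["sample"] = {**sample_meta, **merged["sample"]}
    for sec, items in merged.items():
        if sec not in sections:
            raise ValueError(f"unknown report section {sec!r}")
        for key, val in items.items():
            if isinstance(val, tuple) and len(val) == 2:
                sections[sec][key] = (val[0], val[1])
            else:
                sections[sec][key] = (val, "")
    missing = {
        sec: [item for item in SECTION_ITEMS[sec] if item not in sections[sec]]
        for sec in SECTION_ITEMS
    }
    prov = dict(provenance or {})
    try:
        from . import __version__
        prov.setdefault("toolkit_version", __version__)
    except Exception:
        pass
    content = repr(sorted((s, sorted(d.items())) for s, d in sections.items()))
    prov.setdefault("content_hash", hashlib.sha256(content.encode()).hexdigest()[:16])
    return GuidelineReport(sections=sections, missing=missing, provenance=prov)
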