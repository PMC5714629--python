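"""Render comparison reports: XML for software agents, HTML for humans.

The XML rendering is deterministic and round-trips losslessly back into an
equal :class:`~planverify.comparison.ComparisonReport`, so downstream
tooling can consume verdicts programmatically.  The HTML renderings are
self-contained single files (printable, archivable) showing the plan key,
both database identities, the verdict and every difference grouped by
field.  A batch run is written to a run directory::

    <out>/summary.html
    <out>/plans/<encoded key>.xml
    <out>/plans/<encoded key>.html

with the summary linking relatively to the per-plan reports.
"""

from __future__ import annotations

import html
import urllib.parse
from pathlib import Path
from typing import Iterable

from lxml import etree

from .comparison import (
    ComparisonReport,
    DiffKind,
    DiffPath,
    Difference,
    SummaryReport,
)
from .plan_model import PlanKey

__all__ = [
    "render_report_xml",
    "parse_report_xml",
    "render_report_html",
    "render_summary_html",
    "write_run_directory",
    "report_basename",
]

USER_LIST_BANNER = "Plan list provided by user! Some active plans may be missing!"


# ---------------------------------------------------------------------------
# XML


def render_report_xml(report: ComparisonReport) -> str:
    root = etree.Element(
        "ComparisonReport",
        verdict=report.verdict,
        ref_source=report.ref_source,
        test_source=report.test_source,
        timestamp=report.timestamp,
    )
    etree.SubElement(
        root,
        "Key",
        patient_id=report.key.patient_id,
        course_id=report.key.course_id,
        plan_id=report.key.plan_id,
    )
    diffs_el = etree.SubElement(root, "Differences")
    for d in report.differences:
        _write_diff(diffs_el, d)
    info_el = etree.SubElement(root, "Informational")
    for d in report.informational:
        _write_diff(info_el, d)
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


def _write_diff(parent: etree._Element, d: Difference) -> None:
    el = etree.SubElement(parent, "Difference", kind=d.kind.value, parameter=d.path.parameter)
    if d.path.field_id is not None:
        el.set("field_id", d.path.field_id)
    if d.path.cp_index is not None:
        el.set("cp_index", str(d.path.cp_index))
    if d.path.leaf_index is not None:
        el.set("leaf_index", str(d.path.leaf_index))
    etree.SubElement(el, "Ref").text = d.ref_value
    etree.SubElement(el, "Test").text = d.test_value


def parse_report_xml(text: str | bytes) -> ComparisonReport:
    """Inverse of :func:`render_report_xml`."""
    if isinstance(text, str):
        text = text.encode("utf-8")
    root = etree.fromstring(text)
    if root.tag != "ComparisonReport":
        raise ValueError(f"root element is {root.tag!r}, expected ComparisonReport")
    key_el = root.find("Key")
    if key_el is None:
        raise ValueError("missing Key element")
    key = PlanKey(
        patient_id=key_el.get("patient_id") or "",
        course_id=key_el.get("course_id") or "",
        plan_id=key_el.get("plan_id") or "",
    )

    def read_diffs(tag: str) -> tuple[Difference, ...]:
        parent = root.find(tag)
        if parent is None:
            return ()
        return tuple(_read_diff(el) for el in parent)

    return ComparisonReport(
        key=key,
        verdict=root.get("verdict") or "fail",
        differences=read_diffs("Differences"),
        informational=read_diffs("Informational"),
        ref_source=root.get("ref_source", ""),
        test_source=root.get("test_source", ""),
        timestamp=root.get("timestamp", ""),
    )


def _read_diff(el: etree._Element) -> Difference:
    cp = el.get("cp_index")
    leaf = el.get("leaf_index")
    ref_el, test_el = el.find("Ref"), el.find("Test")
    return Difference(
        path=DiffPath(
            parameter=el.get("parameter") or "",
            field_id=el.get("field_id"),
            cp_index=None if cp is None else int(cp),
            leaf_index=None if leaf is None else int(leaf),
        ),
        kind=DiffKind(el.get("kind")),
        ref_value=(ref_el.text or "") if ref_el is not None else "",
        test_value=(test_el.text or "") if test_el is not None else "",
    )


# ---------------------------------------------------------------------------
# HTML

_PAGE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
h1 {{ font-size: 1.3em; }}
.pass {{ color: #070; font-weight: bold; }}
.fail {{ color: #a00; font-weight: bold; }}
.banner {{ background: #fe8; padding: 0.5em; border: 1px solid #ca0; margin: 1em 0; }}
.sources {{ background: #eef; padding: 0.5em; margin: 1em 0; }}
table {{ border-collapse: collapse; margin: 1em 0; }}
th, td {{ border: 1px solid #999; padding: 0.3em 0.6em; text-align: left; }}
caption {{ text-align: left; font-weight: bold; padding: 0.3em 0; }}
</style>
</head>
<body>
{body}
</body>
</html>
"""


def _esc(text: str) -> str:
    return html.escape(str(text), quote=True)


def _verdict_span(verdict: str) -> str:
    css = "pass" if verdict == "pass" else "fail"
    return f'<span class="{css}">{_esc(verdict.upper())}</span>'


def _sources_block(ref_source: str, test_source: str) -> str:
    # database-identity echo: the operator must confirm the right two
    # databases were compared (wrong-database selection is a known hazard)
    return (
        '<div class="sources">Reference database: <b>%s</b><br>'
        "Test database: <b>%s</b></div>" % (_esc(ref_source), _esc(test_source))
    )


def render_report_html(report: ComparisonReport) -> str:
    """Self-contained HTML page for one plan comparison.

    Every difference appears exactly once, grouped by field; reports are
    never truncated, however long.
    """
    key = report.key.render()
    parts = [f"<h1>Plan comparison: {_esc(key)}</h1>"]
    parts.append(_sources_block(report.ref_source, report.test_source))
    parts.append(f"<p>Verdict: {_verdict_span(report.verdict)}</p>")
    if report.timestamp:
        parts.append(f"<p>Compared at {_esc(report.timestamp)}</p>")

    if report.informational:
        parts.append("<table><caption>Informational (not failing)</caption>")
        parts.append("<tr><th>Parameter</th><th>Reference</th><th>Test</th></tr>")
        for d in report.informational:
            parts.append(
                f"<tr><td>{_esc(d.path.render())}</td>"
                f"<td>{_esc(d.ref_value)}</td><td>{_esc(d.test_value)}</td></tr>"
            )
        parts.append("</table>")

    if not report.differences:
        parts.append("<p>No differences between the reference and test plan.</p>")
    else:
        parts.append(f"<p>{len(report.differences)} difference(s) found.</p>")
        by_field: dict[str, list[Difference]] = {}
        for d in report.differences:
            by_field.setdefault(d.path.field_id or "(plan level)", []).append(d)
        for fid, diffs in by_field.items():
            parts.append(f"<table><caption>Field {_esc(fid)}</caption>")
            parts.append(
                "<tr><th>Location</th><th>Kind</th><th>Reference</th><th>Test</th></tr>"
            )
            for d in diffs:
                loc = d.path.parameter
                if d.path.cp_index is not None:
                    loc += f" @ cp {d.path.cp_index}"
                if d.path.leaf_index is not None:
                    loc += f", leaf {d.path.leaf_index}"
                parts.append(
                    f"<tr><td>{_esc(loc)}</td><td>{_esc(d.kind.value)}</td>"
                    f"<td>{_esc(d.ref_value)}</td><td>{_esc(d.test_value)}</td></tr>"
                )
            parts.append("</table>")

    return _PAGE.format(title=_esc(f"Plan comparison: {key}"), body="\n".join(parts))


def report_basename(key: PlanKey) -> str:
    """Filesystem-safe basename for a per-plan report."""
    return urllib.parse.quote(key.render(), safe=" ._-()")


def render_summary_html(summary: SummaryReport, link_dir: str = "plans") -> str:
    """Self-contained HTML summary over the whole plan list."""
    parts = ["<h1>Plan comparison summary</h1>"]
    parts.append(_sources_block(summary.ref_source, summary.test_source))
    if summary.user_list_banner:
        parts.append(f'<div class="banner">{_esc(USER_LIST_BANNER)}</div>')
    k, n = summary.completed
    parts.append(f"<p>Completed: {k}/{n}</p>")
    if summary.timestamp:
        parts.append(
            f"<p>Run at {_esc(summary.timestamp)}"
            f" (elapsed {summary.elapsed_seconds:.1f} s)</p>"
        )
    parts.append("<table><caption>Results</caption>")
    parts.append("<tr><th>Plan</th><th>Verdict</th><th>Notes</th><th>Report</th></tr>")
    for e in summary.entries:
        link = ""
        if e.report is not None:
            name = report_basename(e.key)
            href = f"{link_dir}/{urllib.parse.quote(name)}.html"
            link = f'<a href="{href}">report</a>'
        css = "pass" if e.verdict == "pass" else "fail"
        parts.append(
            f"<tr><td>{_esc(e.key.render())}</td>"
            f'<td class="{css}">{_esc(e.verdict)}</td>'
            f"<td>{_esc(e.annotation)}</td><td>{link}</td></tr>"
        )
    parts.append("</table>")
    if summary.reference_only_plans:
        parts.append(
            "<table><caption>Plans present only in the reference corpus "
            "(newly imported; not expected in the test corpus)</caption>"
        )
        parts.append("<tr><th>Plan</th></tr>")
        for key in summary.reference_only_plans:
            parts.append(f"<tr><td>{_esc(key.render())}</td></tr>")
        parts.append("</table>")
    return _PAGE.format(title="Plan comparison summary", body="\n".join(parts))


def write_run_directory(summary: SummaryReport, out_dir) -> Path:
    """Write summary.html plus per-plan XML/HTML reports under *out_dir*."""
    out = Path(out_dir)
    plans_dir = out / "plans"
    plans_dir.mkdir(parents=True, exist_ok=True)
    for e in summary.entries:
        if e.report is None:
            continue
        base = report_basename(e.key)
        (plans_dir / f"{base}.xml").write_text(
            render_report_xml(e.report), encoding="utf-8"
        )
        (plans_dir / f"{base}.html").write_text(
            render_report_html(e.report), encoding="utf-8"
        )
    (out / "summary.html").write_text(render_summary_html(summary), encoding="utf-8")
    return out
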