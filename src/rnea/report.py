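"""CSV and HTML rendering of ranked enrichment tables.

Both renderings carry identical formatted values; p-values below 1e-4
switch to scientific notation.  The HTML tables are sortable client-side
via a small embedded script (numeric columns sort numerically).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .enrichment import EnrichmentResult

COLUMNS = ("category_id", "type", "partition", "k", "K", "n", "N",
           "p", "p_adj", "rank", "de_members")

_NUMERIC_COLS = {"k", "K", "n", "N", "p", "p_adj", "rank"}


def _fmt_p(p: float) -> str:
    # %.6g flips to scientific notation exactly below 1e-4
    return f"{p:.6g}"


def table_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Ranked enrichment results as a DataFrame with formatted p-values."""
    rows = [{
        "category_id": r.category_id,
        "type": r.category_type,
        "partition": r.partition,
        "k": r.k, "K": r.K, "n": r.n, "N": r.N,
        "p": _fmt_p(r.p), "p_adj": _fmt_p(r.p_adj), "rank": r.rank,
        "de_members": ";".join(r.de_members),
    } for r in results]
    return pd.DataFrame(rows, columns=list(COLUMNS))


def write_csv(results: list[EnrichmentResult], path: str | Path) -> Path:
    path = Path(path)
    table_frame(results).to_csv(path, index=False, lineterminator="\n")
    return path


_SORT_SCRIPT = """
function sortBy(th) {
  var table = th.closest('table'), tbody = table.tBodies[0];
  var col = th.cellIndex, dir = th.dataset.dir === 'asc' ? -1 : 1;
  th.dataset.dir = dir === 1 ? 'asc' : 'desc';
  var rows = Array.from(tbody.rows);
  rows.sort(function (a, b) {
    var x = a.cells[col].textContent, y = b.cells[col].textContent;
    var nx = parseFloat(x), ny = parseFloat(y);
    if (!isNaN(nx) && !isNaN(ny)) return dir * (nx - ny);
    return dir * x.localeCompare(y);
  });
  rows.forEach(function (r) { tbody.appendChild(r); });
}
""".strip()

_STYLE = ("table{border-collapse:collapse;font-family:sans-serif;"
          "font-size:13px}th,td{border:1px solid #999;padding:3px 7px}"
          "th{cursor:pointer;background:#eee}")


def write_html(results: list[EnrichmentResult], path: str | Path,
               title: str = "Enrichment") -> Path:
    """One sortable HTML table; valid (header-only) even when empty."""
    path = Path(path)
    frame = table_frame(results)
    head = "".join(f'<th onclick="sortBy(this)">{c}</th>' for c in COLUMNS)
    body_rows = []
    for _, row in frame.iterrows():
        cells = "".join(f"<td>{row[c]}</td>" for c in COLUMNS)
        body_rows.append(f"<tr>{cells}</tr>")
    html = (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        f"<title>{title}</title><style>{_STYLE}</style>"
        f"<script>{_SORT_SCRIPT}</script></head>\n"
        f"<body><h1>{title}</h1>\n<table><thead><tr>{head}</tr></thead>"
        f"<tbody>\n{''.join(body_rows)}\n</tbody></table></body></html>\n")
    path.write_text(html, encoding="utf-8")
    return path
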