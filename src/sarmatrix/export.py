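"""Matrix export: color-coded HTML (an R-group-table-like view), flat
TSV, and JSON.  All output is byte-stable for fixed input: ordering is
inherited from the deterministic matrix layout and no timestamps or
environment details are embedded."""

from __future__ import annotations

import html
import json
from pathlib import Path
from typing import Sequence

from .colors import (
    ColorScale, GLOBAL, PER_MATRIX, hex_color, potency_color,
    promiscuity_color, scale_for_values,
)
from .matrices import SARM, sarm_to_dict, write_matrix_tsv
from .multitarget import CSM, csm_to_dict, promiscuity_degree

_PAGE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>{title}</title>
<style>
table {{ border-collapse: collapse; font-family: monospace; }}
th, td {{ border: 1px solid #888; padding: 4px 8px; text-align: center; }}
th {{ background: #eee; font-weight: normal; }}
caption {{ text-align: left; padding: 4px; font-family: sans-serif; }}
</style>
</head>
<body>
<table>
<caption>{caption}</caption>
{header}
{body}
</table>
</body>
</html>
"""


def _auto_scale(matrix: SARM | CSM) -> ColorScale:
    if isinstance(matrix, CSM):
        degrees = [promiscuity_degree(c) for _, _, c in matrix.iter_cells()
                   if c.is_real]
        degrees = [d for d in degrees if d is not None]
        return scale_for_values("promiscuity", [0.0, float(max(degrees or [1]))])
    pkis = [c.pki for _, _, c in matrix.iter_cells() if c.annotated]
    return scale_for_values("potency", pkis)


def _cell_html(matrix: SARM | CSM, cell, scale: ColorScale) -> str:
    if isinstance(matrix, CSM):
        degree = promiscuity_degree(cell)
        color = promiscuity_color(degree, scale)
        if cell.is_real:
            profile = ",".join(sorted(cell.target_profile)) or "none"
            tip = f"{cell.compound_id} | targets: {profile}"
            text = str(degree)
        else:
            tip, text = html.escape(cell.structure), ""
    else:
        color = potency_color(cell.pki, scale) if cell.is_real else (255, 255, 255)
        if cell.is_real:
            pki = "n/a" if cell.pki is None else f"{cell.pki:.2f}"
            tip = f"{cell.compound_id} | pKi {pki}"
            text = pki
        else:
            tip, text = html.escape(cell.structure), ""
    return (f'<td style="background:{hex_color(color)}" '
            f'title="{html.escape(tip, quote=True)}">{text}</td>')


def matrix_html(matrix: SARM | CSM, scale: ColorScale | None = None) -> str:
    """Render one matrix as a standalone HTML table: rows are cores
    (structure strings shown), columns are substituent combinations,
    cells are color-coded with a compound tooltip."""
    if scale is None:
        scale = _auto_scale(matrix)
    header = ("<tr><th>core \\ substituents</th>"
              + "".join(f"<th>{html.escape('.'.join(col))}</th>"
                        for col in matrix.columns)
              + "</tr>")
    rows = []
    for ri, core in enumerate(matrix.rows):
        cells = "".join(
            _cell_html(matrix, matrix.cells[(ri, ci)], scale)
            for ci in range(matrix.n_columns)
        )
        rows.append(f"<tr><th>{html.escape(core)}</th>{cells}</tr>")
    caption = (f"{matrix.matrix_id} | level {matrix.level} | "
               f"{matrix.n_rows}x{matrix.n_columns} | "
               f"scale {scale.kind} [{scale.low:g}, {scale.high:g}] "
               f"({scale.mode})")
    return _PAGE.format(title=html.escape(matrix.matrix_id),
                        caption=html.escape(caption),
                        header=header, body="\n".join(rows))


def export_matrix(
    matrix: SARM | CSM,
    path: str | Path,
    fmt: str = "html",
    scale: ColorScale | None = None,
) -> Path:
    """Write one matrix in the requested format and return the path."""
    path = Path(path)
    if fmt == "html":
        path.write_text(matrix_html(matrix, scale), encoding="utf-8")
    elif fmt == "json":
        data = csm_to_dict(matrix) if isinstance(matrix, CSM) else sarm_to_dict(matrix)
        path.write_text(json.dumps(data, indent=1, sort_keys=True) + "\n",
                        encoding="utf-8")
    elif fmt == "tsv":
        if isinstance(matrix, CSM):
            _write_csm_tsv(matrix, path)
        else:
            write_matrix_tsv(matrix, path)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected html, tsv, json)")
    return path


def _write_csm_tsv(csm: CSM, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("row\tcolumn\tcore\tvalues\tstatus\tcompound_id\t"
                 "promiscuity\ttarget_profile\n")
        for ri, ci, cell in csm.iter_cells():
            values = ".".join(csm.columns[ci])
            degree = promiscuity_degree(cell)
            fh.write(f"{ri}\t{ci}\t{csm.rows[ri]}\t{values}\t{cell.status}\t"
                     f"{cell.compound_id or ''}\t"
                     f"{'' if degree is None else degree}\t"
                     f"{','.join(sorted(cell.target_profile))}\n")


def global_scale(matrices: Sequence[SARM], kind: str = "potency") -> ColorScale:
    """One scale spanning every annotated value in ``matrices``."""
    values = [c.pki for m in matrices for _, _, c in m.iter_cells()
              if c.annotated]
    return scale_for_values(kind, values, mode=GLOBAL)
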