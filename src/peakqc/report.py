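"""Dataset/peptide/run-level summaries of model output, with a heatmap-style
HTML (or PDF) report.

The central object is a per-peptide fragment x run status matrix: each cell
is the model verdict for one transition pair in one run ('ok', 'flag', or
missing when the pair was absent). From it come flag rates per fragment and
per run, and the list of "systematic" fragments — fragments flagged in at
least a configurable fraction of runs (default half), which usually marks
recurring interference on that transition and suggests removing it from
quantitation.
"""

from __future__ import annotations

import base64
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io_skyline import write_table

MISSING = "missing"


@dataclass
class QCSummary:
    """Status matrices and flag rates at peptide, fragment and run level."""

    peptide_matrices: dict          # peptide -> DataFrame fragment x run
    fragment_rates: pd.DataFrame    # peptide, fragment, n_runs, n_flagged, flag_rate, systematic
    run_rates: pd.DataFrame         # run, n_pairs, n_flagged, flag_rate
    total_pairs: int
    total_flagged: int
    systematic_fraction: float

    @property
    def flag_rate(self) -> float:
        return self.total_flagged / self.total_pairs if self.total_pairs else 0.0

    def systematic_fragments(self) -> pd.DataFrame:
        return self.fragment_rates[self.fragment_rates["systematic"]]


def summarize(predictions: pd.DataFrame,
              systematic_fraction: float = 0.5) -> QCSummary:
    """Build the QC summary from a predictions table.

    ``predictions`` needs FileName, PeptideModifiedSequence, FragmentIon
    (+ ProductCharge) and status columns; row order is irrelevant. Missing
    pairs are excluded from every rate denominator.
    """
    df = predictions.copy()
    df["fragment"] = df["FragmentIon"].astype(str)
    if "ProductCharge" in df:
        multi = df.groupby("FragmentIon")["ProductCharge"].nunique()
        if (multi > 1).any():  # disambiguate only when charges actually differ
            df["fragment"] = df["FragmentIon"].astype(str) + "/" + df["ProductCharge"].astype(str)
    runs = sorted(df["FileName"].unique())
    matrices = {}
    frag_records = []
    for pep, sub in df.groupby("PeptideModifiedSequence", sort=True):
        mat = (sub.pivot_table(index="fragment", columns="FileName",
                               values="status", aggfunc="first")
               .reindex(columns=runs))
        mat = mat.fillna(MISSING)
        matrices[pep] = mat
        for frag, row in mat.iterrows():
            present = row[row != MISSING]
            n_flag = int((present == "flag").sum())
            rate = n_flag / len(present) if len(present) else 0.0
            frag_records.append({
                "PeptideModifiedSequence": pep, "fragment": frag,
                "n_runs": len(present), "n_flagged": n_flag,
                "flag_rate": rate,
                "systematic": rate >= systematic_fraction and len(present) > 0})
    run_records = []
    for run, sub in df.groupby("FileName", sort=True):
        n_flag = int((sub["status"] == "flag").sum())
        run_records.append({"FileName": run, "n_pairs": len(sub),
                            "n_flagged": n_flag,
                            "flag_rate": n_flag / len(sub) if len(sub) else 0.0})
    return QCSummary(
        peptide_matrices=matrices,
        fragment_rates=pd.DataFrame(
            frag_records, columns=["PeptideModifiedSequence", "fragment",
                                   "n_runs", "n_flagged", "flag_rate",
                                   "systematic"]),
        run_rates=pd.DataFrame(run_records,
                               columns=["FileName", "n_pairs", "n_flagged",
                                        "flag_rate"]),
        total_pairs=len(df), total_flagged=int((df["status"] == "flag").sum()),
        systematic_fraction=systematic_fraction)


def write_summary(summary: QCSummary, path) -> None:
    """Write qc_summary.csv (fragment-level rates + systematic marks)."""
    write_table(path, summary.fragment_rates)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_CELL_STYLE = {"ok": "background:#2e7d32;color:white",
               "flag": "background:#c62828;color:white",
               MISSING: "background:#bdbdbd;color:#424242"}

_PAGE_CSS = """
body { font-family: sans-serif; margin: 2em; }
table.heatmap { border-collapse: collapse; font-size: 11px; }
table.heatmap td, table.heatmap th { border: 1px solid #fff; padding: 3px 6px; }
h2 { border-bottom: 1px solid #888; }
"""


def _heatmap_html(mat: pd.DataFrame) -> str:
    head = "".join(f"<th>{c}</th>" for c in mat.columns)
    rows = []
    for frag, row in mat.iterrows():
        cells = "".join(
            f'<td style="{_CELL_STYLE.get(v, "")}" title="{v}">'
            f'{"" if v == MISSING else v}</td>' for v in row)
        rows.append(f"<tr><th>{frag}</th>{cells}</tr>")
    return (f'<table class="heatmap"><tr><th>fragment \\ run</th>{head}</tr>'
            + "".join(rows) + "</table>")


def _probability_hist_png(probs: np.ndarray) -> str:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 2.2), dpi=100)
    ax.hist(probs, bins=np.linspace(0, 1, 21), color="#546e7a")
    ax.axvline(0.5, color="#c62828", lw=1)
    ax.set_xlabel("flag probability")
    ax.set_ylabel("pairs")
    buf = io.BytesIO()
    fig.savefig(buf, format="png", metadata={"Software": None},
                bbox_inches="tight")
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode("ascii")


def render_report(summary: QCSummary, predictions: pd.DataFrame, out_path,
                  format: str = "html", traces: Optional[list] = None) -> Path:
    """Render the QC report: one section per peptide with its status
    heatmap and flag-probability distribution, plus dataset totals.

    Deterministic: identical inputs give identical bytes. ``traces``
    (optional) adds representative peak plots for flagged/ok pairs of each
    peptide.
    """
    if format == "pdf":
        return _render_pdf(summary, predictions, out_path, traces)
    html = [f"<html><head><style>{_PAGE_CSS}</style></head><body>",
            "<h1>Peak quality assessment report</h1>"]
    if summary.total_pairs == 0:
        html.append("<p><b>No data:</b> the predictions table is empty.</p>")
    else:
        html.append(
            f"<p>{summary.total_pairs} transition pairs scored; "
            f"{summary.total_flagged} flagged "
            f"({100 * summary.flag_rate:.1f}%).</p>")
        sys_frags = summary.systematic_fragments()
        if len(sys_frags):
            items = "".join(
                f"<li>{r.PeptideModifiedSequence} {r.fragment}: flagged in "
                f"{r.n_flagged}/{r.n_runs} runs</li>"
                for r in sys_frags.itertuples())
            html.append("<h2>Systematically flagged transitions</h2>"
                        f"<ul>{items}</ul>")
        has_probs = "flag_probability" in predictions.columns
        for pep, mat in summary.peptide_matrices.items():
            html.append(f"<h2>{pep}</h2>")
            html.append(_heatmap_html(mat))
            if has_probs:
                probs = predictions.loc[
                    predictions["PeptideModifiedSequence"] == pep,
                    "flag_probability"].to_numpy()
                if len(probs):
                    png = _probability_hist_png(probs)
                    html.append(f'<p><img src="data:image/png;base64,{png}"/></p>')
    html.append("</body></html>")
    out_path = Path(out_path)
    out_path.write_text("\n".join(html))
    return out_path


def _render_pdf(summary: QCSummary, predictions: pd.DataFrame, out_path,
                traces=None) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.backends.backend_pdf import PdfPages

    out_path = Path(out_path)
    code = {"ok": 0, "flag": 1, MISSING: 2}
    with PdfPages(out_path, metadata={"CreationDate": None}) as pdf:
        fig, ax = plt.subplots(figsize=(8, 3))
        ax.axis("off")
        if summary.total_pairs == 0:
            ax.text(0.05, 0.6, "No data: the predictions table is empty.")
        else:
            ax.text(0.05, 0.6,
                    f"{summary.total_pairs} transition pairs scored; "
                    f"{summary.total_flagged} flagged "
                    f"({100 * summary.flag_rate:.1f}%).", fontsize=12)
        ax.set_title("Peak quality assessment report")
        pdf.savefig(fig)
        plt.close(fig)
        for pep, mat in summary.peptide_matrices.items():
            vals = mat.map(lambda v: code.get(v, 2)).to_numpy(dtype=float)
            fig, ax = plt.subplots(
                figsize=(max(4, 0.25 * mat.shape[1]), 1 + 0.4 * mat.shape[0]))
            ax.imshow(vals, aspect="auto", cmap="RdYlGn_r", vmin=0, vmax=2)
            ax.set_yticks(range(mat.shape[0]), mat.index)
            ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=90,
                          fontsize=6)
            ax.set_title(pep)
            pdf.savefig(fig, bbox_inches="tight")
            plt.close(fig)
    return out_path
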