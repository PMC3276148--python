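"""Published-table data and tab-delimited report writers.

Reports mirror the diversity-table layout (one row per segment, floats
printed x10^3 with 2 decimals); a parallel machine-readable file keeps the
raw values.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .diversity import SegmentStats
from .divergence import DivergenceStats


def load_schwerinii_intronic() -> pd.DataFrame:
    """The printed intronic diversity table for S. schwerinii (28 gene
    segments: n, L, S, singletons, theta and pi x10^3, N_h, H_e, Tajima's
    D), shipped with the package as input data."""
    ref = resources.files("locuspair.data") / "schwerinii_intronic.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def _fmt(x: float, scale: float = 1.0, nd: int = 2) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x * scale:.{nd}f}"


def write_diversity_report(path: str | Path,
                           rows: Sequence[tuple[str, SegmentStats]]) -> None:
    """Diversity table: segment, n, L, S(singletons), theta/pi x10^3, N_h,
    H_e, Tajima's D.  Raw per-site values go to '<path>.raw.tsv'."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("segment\tn\tL\tS_singleton\ttheta_e3\tpi_e3\tNh\tHe\tD\n")
        for name, st in rows:
            fh.write(
                f"{name}\t{st.n}\t{st.L}\t{st.S} ({st.n_singleton})\t"
                f"{_fmt(st.theta_per_site, 1e3)}\t{_fmt(st.pi_per_site, 1e3)}\t"
                f"{st.N_h}\t{_fmt(st.H_e, 1, 3)}\t{_fmt(st.tajima_D)}\n"
            )
    raw = pd.DataFrame(
        [{"segment": name, **st.__dict__} for name, st in rows]
    )
    raw.to_csv(path.with_suffix(path.suffix + ".raw.tsv"), sep="\t", index=False)


def write_divergence_report(path: str | Path,
                            rows: Sequence[tuple[str, DivergenceStats]]) -> None:
    """Shared/fixed table per segment plus totals."""
    with open(path, "w") as fh:
        fh.write("segment\tL\tN1\tN2\tS1\tS2\tS_shared\tS_fixed\tFst\tp_perm\n")
        tot = [0] * 5
        for name, d in rows:
            fh.write(
                f"{name}\t{d.L}\t{d.n1}\t{d.n2}\t{d.S1}\t{d.S2}\t"
                f"{d.shared}\t{d.fixed}\t{_fmt(d.fst, 1, 3)}\t{_fmt(d.p_perm, 1, 4)}\n"
            )
            for i, v in enumerate((d.L, d.S1, d.S2, d.shared, d.fixed)):
                tot[i] += v
        fh.write(f"Total\t{tot[0]}\t\t\t{tot[1]}\t{tot[2]}\t{tot[3]}\t{tot[4]}\t\t\n")


def write_ld_report(path: str | Path, rows: Sequence[dict]) -> None:
    """LD pair table: gene, site_i, site_j, dist_bp, r2, p, significant."""
    cols = ["gene", "site_i", "site_j", "dist_bp", "r2", "p_fisher", "significant"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
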