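"""Case-study loaders and fit-report writers."""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import polygons_to_graph
from .laplace import LaplaceFit
from .model import ModelData, ModelInputError, relative_risk
from .rdata import parse_r_vectors, pick_vector

__all__ = [
    "load_case_study",
    "load_bundled_pennsylvania",
    "write_fit_report",
    "read_fit_json",
]

_MS_N_COUNTIES = 82


class CaseStudyError(FileNotFoundError):
    pass


def load_case_study(
    name: str,
    supplement_dir: str | Path,
    contiguity_rule: str = "queen",
    y_var: str | None = None,
    E_var: str | None = None,
    label_field: str | None = None,
) -> ModelData:
    """Load a named case study from its supplementary files.

    ``mississippi``: 2002 human West Nile virus counts for the 82 counties,
    read from ``ms_human_wv_data.R`` (counts and expected counts discovered
    as length-82 numeric vectors — counts all-integer, expected counts not)
    plus queen contiguity from ``mississippi_county.shp``.  Pass ``y_var`` /
    ``E_var`` to resolve ambiguous variable names explicitly.
    """
    if name != "mississippi":
        raise ModelInputError(
            f"unknown case study {name!r}; bundled Pennsylvania data is "
            "available via load_bundled_pennsylvania()"
        )
    supplement_dir = Path(supplement_dir)
    data_file = supplement_dir / "ms_human_wv_data.R"
    shp_file = supplement_dir / "mississippi_county.shp"
    missing = [str(p) for p in (data_file, shp_file) if not p.exists()]
    if missing:
        raise CaseStudyError(
            "missing supplementary file(s): " + ", ".join(missing)
        )
    vectors = parse_r_vectors(data_file)
    if y_var is not None:
        y = vectors[y_var]
    else:
        _, y = pick_vector(
            vectors, _MS_N_COUNTIES, prefer=("y", "count", "case"), integer=True
        )
    if E_var is not None:
        E = vectors[E_var]
    else:
        try:
            _, E = pick_vector(
                vectors, _MS_N_COUNTIES, prefer=("e", "expect"), integer=False
            )
        except Exception:
            yname, _ = pick_vector(
                vectors, _MS_N_COUNTIES, prefer=("y", "count", "case"), integer=True
            )
            _, E = pick_vector(
                vectors, _MS_N_COUNTIES, prefer=("e", "expect"), exclude=(yname,)
            )
    graph = polygons_to_graph(shp_file, contiguity_rule, label_field)
    if graph.n_regions != _MS_N_COUNTIES:
        raise ModelInputError(
            f"expected {_MS_N_COUNTIES} counties, shapefile has {graph.n_regions}"
        )
    if y.size != graph.n_regions or E.size != graph.n_regions:
        raise ModelInputError("data vectors do not match the number of counties")
    return ModelData(
        y=y, E=E, X=np.empty((graph.n_regions, 0)), graph=graph
    )


def load_bundled_pennsylvania(contiguity_rule: str = "queen") -> ModelData:
    """2002 Pennsylvania lung-cancer counts for 67 counties (bundled).

    Counts are totals over the 16 race x gender x age strata; expected
    counts are indirectly standardized over the same strata (state-wide
    stratum rates times county stratum populations).  Contiguity is derived
    from the bundled county boundary polygons (WKT).
    """
    pkg = resources.files("icarlap") / "data" / "pennsylvania"
    counts = pd.read_csv(str(pkg / "penn_lung_2002.csv"))
    graph = polygons_to_graph(str(pkg / "penn_counties_wkt.csv"), contiguity_rule)
    counts = counts.set_index("county").loc[list(graph.region_labels)]
    return ModelData(
        y=counts["y"].to_numpy(),
        E=counts["E"].to_numpy(),
        X=np.empty((graph.n_regions, 0)),
        graph=graph,
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_fit_report(
    fit: LaplaceFit, data: ModelData, out_dir: str | Path, seed: int | None = None
) -> dict[str, Path]:
    """Write JSON (parameters), CSV (per-region) and a readable text table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    payload = {
        "theta_hat": {
            "beta0": fit.theta_hat.beta0,
            "beta": fit.theta_hat.beta.tolist(),
            "log_tau": fit.theta_hat.log_tau,
        },
        "se_internal": [None if not np.isfinite(v) else float(v) for v in fit.se_theta],
        "report_scale": fit.report_scale,
        "dispersion": fit.dispersion(),
        "dispersion_se": None
        if not np.isfinite(fit.dispersion_se())
        else fit.dispersion_se(),
        "marginal_nll": fit.marginal_nll,
        "max_gradient": fit.max_gradient,
        "gradient_tolerance": 1e-4,
        "converged": fit.converged,
        "at_boundary": fit.at_boundary,
        "n_outer_iterations": fit.n_outer_iterations,
        "constraint": {
            "mode": fit.constraint.mode,
            "soft_precision": fit.constraint.soft_precision,
        },
        "optimizer": "L-BFGS-B with central finite-difference gradients",
        "seed": seed,
    }
    json_path = out_dir / "fit.json"
    json_path.write_text(json.dumps(payload, indent=2))

    lam = relative_risk(fit.theta_hat, fit.s_hat, data)
    csv_path = out_dir / "regions.csv"
    pd.DataFrame(
        {
            "region_label": data.graph.region_labels,
            "y": data.y.astype(int),
            "E": data.E,
            "s_hat": fit.s_hat.s,
            "s_conditional_sd": fit.s_hat.conditional_sd
            if fit.s_hat.conditional_sd is not None
            else np.nan,
            "relative_risk": lam,
            "fitted_count": data.E * lam,
        }
    ).to_csv(csv_path, index=False)

    lines = ["parameter            estimate (SE)"]
    for row in fit.coefficient_table():
        se = "--" if not np.isfinite(row["se"]) else f"{row['se']:.3f}"
        lines.append(f"{row['parameter']:<20s} {row['estimate']: .3f} ({se})")
    verdict = "PASS" if fit.max_gradient <= 1e-4 else "FAIL"
    lines.append(f"max |outer gradient|  {fit.max_gradient:.3e} (tolerance 1e-4: {verdict})")
    if not fit.converged:
        lines.insert(0, "*** WARNING: FIT DID NOT CONVERGE ***")
    if fit.at_boundary:
        lines.append("note: dispersion estimate at the search boundary")
    txt_path = out_dir / "fit.txt"
    txt_path.write_text("\n".join(lines) + "\n")
    return {"json": json_path, "csv": csv_path, "txt": txt_path}


def read_fit_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
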