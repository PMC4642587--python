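"""CSV table I/O for relaxation records and model-free results."""

from __future__ import annotations

import pandas as pd

from .modelfree import MODEL_FREE_PARAMS, ModelFreeResult, RelaxationRecord

RATES_COLUMNS = ["res_seq", "R1", "R1_err", "R2", "R2_err", "NOE", "NOE_err"]


def records_to_frame(records: list[RelaxationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "res_seq": [r.res_seq for r in records],
            "R1": [r.R1 for r in records],
            "R1_err": [r.sigma_R1 for r in records],
            "R2": [r.R2 for r in records],
            "R2_err": [r.sigma_R2 for r in records],
            "NOE": [r.NOE for r in records],
            "NOE_err": [r.sigma_NOE for r in records],
        }
    )


def frame_to_records(df: pd.DataFrame) -> list[RelaxationRecord]:
    missing = [c for c in RATES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rates table lacks columns: {missing}")
    return [
        RelaxationRecord(
            res_seq=int(row.res_seq),
            R1=float(row.R1), R2=float(row.R2), NOE=float(row.NOE),
            sigma_R1=float(row.R1_err), sigma_R2=float(row.R2_err),
            sigma_NOE=float(row.NOE_err),
        )
        for row in df.itertuples()
    ]


def read_rates_csv(path) -> list[RelaxationRecord]:
    return frame_to_records(pd.read_csv(path))


def write_rates_csv(records: list[RelaxationRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def modelfree_results_to_frame(results: dict[int, ModelFreeResult]) -> pd.DataFrame:
    rows = []
    for res_seq in sorted(results):
        r = results[res_seq]
        if r.params is None:
            rows.append({"res_seq": res_seq, "model": 0, "S2": None, "tau_e": None,
                         "Rex": None, "S2f": None, "chi2": None})
            continue
        p = r.params
        row = {"res_seq": res_seq, "model": p.model_id, "S2": p.S2, "tau_e": p.tau_e,
               "Rex": p.R_ex, "S2f": p.S2_f, "chi2": r.chi2}
        for name in MODEL_FREE_PARAMS[p.model_id]:
            if name in r.mc_errors:
                key = {"S2": "S2_err", "tau_e": "tau_e_err",
                       "R_ex": "Rex_err", "S2_f": "S2f_err"}[name]
                row[key] = r.mc_errors[name]
        rows.append(row)
    return pd.DataFrame(rows)
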