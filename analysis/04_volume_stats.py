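#!/usr/bin/env python
"""Volume-level statistics: predicted volume vs reference infarct volume.

Applies, per group, the pooled Dice- and Youden-optimal ATI thresholds
(from step 03) and the vendor-default ATS rule (relative MTT > 150%,
CBV < 2 ml/100 g) to every subject, converts the binary predictions to
millilitres, and reports Pearson correlations with the reference volume,
the Steiger-type comparison of the dependent ATI-vs-ATS correlations,
and Wilcoxon group comparisons.
"""

import sys
from pathlib import Path

import pandas as pd

from ctperf.alignment import make_eval_mask
from ctperf.cohort import build_report, correlate_volumes, mask_volume, steiger_z
from ctperf.io import load_map_set, load_subject
from ctperf.threshold_eval import TABLE_GRIDS, ats_default_prediction, binarize

SCRATCH = Path("scratch/cohort")
MAPS = Path("scratch/maps")
RESULTS = Path("results")
FOCUS = {"A": "tmax", "B": "cbf_rel"}
ATS_TARGET = {"A": "hypoperfused", "B": "core"}


def main() -> int:
    opts = pd.read_csv(RESULTS / "optimal_thresholds.csv").set_index(
        ["group", "algorithm", "parameter", "criterion"])
    subject_ids = sorted(p.name.split("_")[0]
                         for p in SCRATCH.glob("*_ctp.nii.gz"))

    rows = []
    for sid in subject_ids:
        study, fiv, _ = load_subject(SCRATCH, sid)
        g = study.group
        param = FOCUS[g]
        grid = TABLE_GRIDS[param]
        ati = load_map_set(MAPS, sid, "ati")
        ats = load_map_set(MAPS, sid, "ats")
        em_ati = make_eval_mask(study, ati) & ati.validity(param)
        em_ats = make_eval_mask(study, ats)
        row = {"subject_id": sid, "group": g,
               "fiv_volume_ml": mask_volume(fiv & em_ati, study.voxel_size)}
        for crit in ("dice", "youden"):
            thr = float(opts.loc[(g, "ati", param, crit), "threshold"])
            pred = binarize(ati[param], thr, grid.direction, em_ati)
            row[f"ati_{crit}_volume_ml"] = mask_volume(pred, study.voxel_size)
        pred_ats = ats_default_prediction(ats, target=ATS_TARGET[g]) & em_ats
        row["ats_default_volume_ml"] = mask_volume(pred_ats, study.voxel_size)
        rows.append(row)
    subj = pd.DataFrame(rows)

    corr_rows = []
    for g, sub in subj.groupby("group"):
        fiv_v = sub["fiv_volume_ml"].to_numpy()
        rs = {}
        for col in ("ati_dice_volume_ml", "ati_youden_volume_ml",
                    "ats_default_volume_ml"):
            rs[col] = correlate_volumes(sub[col].to_numpy(), fiv_v)
            corr_rows.append({"group": g, "configuration": col,
                              "pearson_r": rs[col], "n": len(sub)})
        for crit in ("dice", "youden"):
            r23 = correlate_volumes(sub[f"ati_{crit}_volume_ml"].to_numpy(),
                                    sub["ats_default_volume_ml"].to_numpy())
            _, p = steiger_z(rs[f"ati_{crit}_volume_ml"],
                             rs["ats_default_volume_ml"], r23, len(sub))
            corr_rows.append({"group": g,
                              "configuration": f"ati_{crit}_vs_ats_p",
                              "pearson_r": p, "n": len(sub)})
    corr = pd.DataFrame(corr_rows)

    auc = pd.read_csv(RESULTS / "auc.csv")
    report = build_report(subj, auc,
                          pd.read_csv(RESULTS / "optimal_thresholds.csv"),
                          corr)
    subj.to_csv(RESULTS / "subject_volumes.csv", index=False,
                float_format="%.6g")
    corr.to_csv(RESULTS / "correlations.csv", index=False, float_format="%.6g")
    report["group_characteristics"].to_csv(
        RESULTS / "group_characteristics.csv", index=False,
        float_format="%.6g")

    for g, sub in corr.groupby("group"):
        label = "penumbra" if g == "A" else "core"
        print(f"group {g} ({label} estimation), "
              f"n={int(sub.n.iloc[0])}:")
        for _, r in sub.iterrows():
            kind = "p" if r.configuration.endswith("_p") else "r"
            print(f"  {r.configuration:<28s} {kind} = {r.pearson_r:+.3f}")
    gc = report["group_characteristics"]
    fiv = gc[gc.characteristic == "fiv_volume_ml"].iloc[0]
    print(f"reference volume A vs B: {fiv.mean_a:.1f} vs {fiv.mean_b:.1f} ml "
          f"(Wilcoxon p = {fiv.p_value:.3f})")
    print(f"tables -> {RESULTS}/subject_volumes.csv, correlations.csv, "
          "group_characteristics.csv")
    return 0


if __name__ == "__main__":
    sys.exit(main())
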