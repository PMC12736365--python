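"""Model-evaluation diagnostics: GOF residual table and pcVPC.

Re-fits are not repeated here: the script reuses the fitted parameters from
02_fit_model (or the published values if no fit table is present), computes a
goodness-of-fit table (PRED/IPRED/IWRES/CWRES per observation) and a
1000-replicate prediction-corrected visual predictive check, and writes both
as numeric tables ready for plotting.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from fludapk import RandomEffectsSpec, cv_percent, gof_table, pcvpc, read_dataset
from fludapk.estimation import FitResult, final_model, map_estimate


def load_fit(out: Path, seed: int, dataset):
    fit_path = out / f"fit_seed{seed}.csv"
    theta_names = [
        "theta_cart1", "theta_cart2", "theta_crcl", "theta_v1",
        "theta_v2", "theta_v3", "theta_cld2", "theta_cld3",
    ]
    if fit_path.exists():
        table = pd.read_csv(fit_path).set_index("parameter")["estimate"]
        theta = {k: float(table[k]) for k in theta_names}
        w_cl = cv_percent(float(table["IIV_CL_CV_pct"]), inverse=True)
        w_v1 = cv_percent(float(table["IIV_V1_CV_pct"]), inverse=True)
        off = float(table["corr_CL_V1"]) * np.sqrt(w_cl * w_v1)
        spec = RandomEffectsSpec(
            omega=np.array([[w_cl, off], [off, w_v1]]), sigma=float(table["sigma_log"])
        )
        print(f"using fitted parameters from {fit_path}")
    else:
        from fludapk import ThetaVector
        from fludapk.estimation import theta_to_dict

        theta = theta_to_dict(ThetaVector())
        spec = RandomEffectsSpec()
        print("no fit table found; using published estimates")
    ebes = {s.id: map_estimate(s, theta, spec)[0] for s in dataset}
    return FitResult(
        theta_hat=theta, spec_hat=spec, ofv=float("nan"), ebes=ebes,
        iwres=np.zeros(0), model=final_model(), convergence="loaded", n_iter=0,
    )


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-sim", type=int, default=1000)
    args = ap.parse_args()

    dataset = read_dataset(args.out / f"study_seed{args.seed}.csv")
    fit = load_fit(args.out, args.seed, dataset)

    gof = gof_table(fit, dataset)
    gof.to_csv(args.out / f"gof_seed{args.seed}.csv", index=False)
    print(f"GOF: {len(gof)} observations; CWRES mean {gof.cwres.mean():+.3f}, "
          f"SD {gof.cwres.std():.3f}")

    vpc = pcvpc(fit, dataset, n_sim=args.n_sim, seed=args.seed)
    frame = vpc.to_frame()
    frame.to_csv(args.out / f"vpc_seed{args.seed}.csv", index=False)
    inside = (vpc.observed >= vpc.sim_lower) & (vpc.observed <= vpc.sim_upper)
    print(f"pcVPC ({args.n_sim} replicates, {len(vpc.bin_times)} bins): "
          f"{100 * inside.mean():.0f}% of observed percentiles inside their 95% PI")
    print(frame.to_string(index=False, float_format=lambda x: f"{x:.2f}"))


if __name__ == "__main__":
    main()
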