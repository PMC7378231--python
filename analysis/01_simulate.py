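#!/usr/bin/env python
"""Generate the synthetic CRPC study used by the downstream analysis steps.

Emulates the study design: a benign(6)/Pca(8)/CRPC(6) tissue cohort with
planted Type_A/Type_B up-regulation, LNCaP/VCaP DHT-stimulation and 22Rv1
AR-knockdown condition matrices, AR ChIP-seq peaks planted at known TSS
distances, and a merged RefSeq/GENCODE/NONCODE annotation containing
antisense, intergenic and exonic-decoy lncRNAs. Writes everything plus the
ground-truth manifest under results/analysis/sim/.
"""

from pathlib import Path

from crpclnc.simulate import SimulationConfig, simulate

ROOT = Path(__file__).resolve().parents[1]
SIM_DIR = ROOT / "results" / "analysis" / "sim"
SEED = 7


def main() -> None:
    config = SimulationConfig(seed=SEED)
    out = simulate(config, SIM_DIR)
    t = out.ground_truth.table
    print(f"wrote {len(out.paths)} files to {SIM_DIR}")
    print(f"genes: {len(out.genes)} "
          f"({(t['biotype'] == 'coding').sum()} coding, "
          f"{(t['biotype'] == 'noncoding').sum()} noncoding)")
    print("planted classes:", t["true_class"].value_counts().to_dict())
    print("lncRNA contexts:", t["lnc_context"].value_counts().to_dict())
    print(f"AR-bound genes (<= {config.window_target_bp / 1000:.0f} kb): "
          f"{(t['ar_bound'] == 1).sum()}")


if __name__ == "__main__":
    main()
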