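#!/usr/bin/env python
"""Split the phantom putamina into the four AC-anchored quadrants.

The axial plane containing the AC-PC line separates superior from
inferior; the coronal plane through AC, perpendicular to the AC-PC line,
separates anterior from posterior.  Writes per-segment volumetry to
results/parcellation_volumes.csv.
"""

from pathlib import Path

import pandas as pd

from cedplan import PhantomSpec, build_acpc_frame, generate_phantom, parcellate_putamen

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ph = generate_phantom(PhantomSpec(seed=42, jitter_mm=1.5))
    frame = build_acpc_frame(**ph.landmarks)
    rows = []
    for hemi, mask in ph.putamen_masks.items():
        parc = parcellate_putamen(mask, frame, hemisphere=hemi)
        df = parc.to_frame()
        df.insert(0, "hemisphere", hemi)
        rows.append(df)
        total = sum(parc.volumes_mm3.values())
        print(f"{hemi} putamen {total:.0f} mm^3 -> " + ", ".join(
            f"{k} {v:.0f}" for k, v in parc.volumes_mm3.items()))
    OUT.mkdir(exist_ok=True)
    pd.concat(rows).to_csv(OUT / "parcellation_volumes.csv", index=False)
    print(f"table written to {OUT / 'parcellation_volumes.csv'}")


if __name__ == "__main__":
    main()
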