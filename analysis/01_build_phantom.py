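#!/usr/bin/env python
"""Build one labeled digital phantom subject and write it to disk.

The phantom stands in for a co-registered patient dataset: brain mask,
per-hemisphere putamen, SMA-like and amygdala-like ROI blobs, ventricle and
vessel surrogates, a tensor field with two planted fiber bundles
(SMA -> superior-posterior putamen, amygdala -> inferior-posterior
putamen), AC/PC/superior landmarks, and frontal/occipital entry-target
pairs.  Everything below is reproducible from the seed.
"""

from pathlib import Path

from cedplan import PhantomSpec, generate_phantom
from cedplan.phantom import attach_dwi, write_phantom

OUT = Path(__file__).resolve().parents[1] / "results" / "phantom_subject00"


def main() -> None:
    spec = PhantomSpec(seed=42, jitter_mm=1.5)
    ph = attach_dwi(generate_phantom(spec))
    out = write_phantom(ph, OUT)
    print(f"phantom written to {out}")
    print(f"  grid {spec.grid_shape} at {spec.voxel_size} mm isotropic")
    print(f"  brain voxels: {int(ph.brain_mask.data.sum())}")
    for hemi, v in ph.putamen_masks.items():
        print(f"  putamen {hemi}: {int(v.data.sum())} voxels")
    print(f"  DWI volumes: {ph.dwi_signal.shape[-1]} "
          f"(1 b=0 + {ph.dwi_signal.shape[-1]-1} at b=1000 s/mm^2)")
    print("planted ground-truth connections:")
    print(ph.truth.to_string(index=False))


if __name__ == "__main__":
    main()
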