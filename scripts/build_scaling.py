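"""Regenerate the frozen descriptor-scaling artifact.

Computes raw descriptor vectors for a fixed reference library (simulator
seed 0, 400 analytes) and freezes per-descriptor offset (mean) and scale
(standard deviation, floored) into src/gcri/assets/descriptor_scaling.csv.
Run from the repository root only when the descriptor manifest changes; the
shipped factors must otherwise stay fixed so feature vectors remain
comparable across trainings.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gcri.features import load_manifest, _RDKIT_FUNCS, _FRAGMENT_FUNCS
from gcri.simulate import generate_library
from rdkit.Chem import rdMolDescriptors

manifest = load_manifest()
library = generate_library(400, seed=0)

rows = []
for analyte in library:
    mol = analyte.molecule.mol
    autocorr = None
    vec = []
    for name, provider in manifest.general:
        if provider.startswith("autocorr2d:"):
            if autocorr is None:
                autocorr = rdMolDescriptors.CalcAUTOCORR2D(mol)
            vec.append(autocorr[int(provider.split(":", 1)[1])])
        else:
            try:
                vec.append(_RDKIT_FUNCS[name](mol))
            except Exception:
                vec.append(np.nan)
    for name in manifest.fragments:
        vec.append(_FRAGMENT_FUNCS[name](mol))
    rows.append(vec)

raw = np.array(rows, dtype=np.float64)
with np.errstate(all="ignore"):
    offset = np.nanmean(np.where(np.isfinite(raw), raw, np.nan), axis=0)
    scale = np.nanstd(np.where(np.isfinite(raw), raw, np.nan), axis=0)
offset = np.where(np.isfinite(offset), offset, 0.0)
scale = np.where(np.isfinite(scale) & (scale > 1e-9), scale, 1.0)

out = Path(__file__).resolve().parents[1] / "src" / "gcri" / "assets" / "descriptor_scaling.csv"
pd.DataFrame({"name": manifest.names,
              "offset": np.round(offset, 8),
              "scale": np.round(scale, 8)}).to_csv(out, index=False)
print(f"wrote {out} ({len(manifest.names)} rows)")
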