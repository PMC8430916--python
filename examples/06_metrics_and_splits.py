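"""The accuracy metric suite and compound-based split hygiene."""

from gcri import admit, kfold, metrics
from gcri.data import RetentionRecord
from gcri.chem import parse_molecule

report = metrics([1010, 990, 1030, 1265, 880],
                 [1000, 1005, 1020, 1300, 900])
print("metric suite on five paired (predicted, reference) RIs:")
for field in ("mae", "mdae", "rmse", "mpe", "mdpe", "r2", "coverage90"):
    print(f"  {field:10s} {getattr(report, field):8.3f}")

def rec(smiles, ri):
    return RetentionRecord(molecule=parse_molecule(smiles), phase="DB-5",
                           family="non-polar", ri=ri)

records = [rec("CCCCCCCCCC", 1000.0),          # n-decane: filtered out
           rec("C[Se]C", 600.0),               # selenium: filtered out
           rec("Cc1ccccc1", 760.0),            # toluene: admitted
           rec("CC(C)CO", 620.0)]              # isobutanol: admitted
admitted, rejections = admit(records)
print(f"\nadmission: kept {len(admitted)}, rejected "
      f"{[(r.molecule.canonical_smiles, why) for r, why in rejections]}")

pool = [rec("O" + "C" * n, 400.0 + 100 * n) for n in range(2, 12)]
folds = kfold(pool, k=5, seed=0)
print("5-fold compound partition sizes:", [len(f) for f in folds])
# Folds partition compounds, not records: stereoisomers and replicate
# entries always land in the same fold.
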