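"""Read and clean a mammographic-mass table in the UCI CSV dialect.

The reader takes the 6-field comma-separated dialect (BI-RADS, age, shape,
margin, density, severity; '?' for missing) and reports per-field missing
counts before anything is dropped.  Cleaning removes incomplete records
and out-of-range outliers (BI-RADS outside 1-6, age outside 18-96, ...).
This script writes a small synthetic file in the same dialect; point
``PATH`` at the real UCI mammographic_masses.data download to process the
original study data.
"""

import tempfile
from pathlib import Path

from relaxedcq import clean, read_mammo_csv
from relaxedcq.datasets import MammoRecord, write_mammo_csv

records = [
    MammoRecord(5, 67, 3, 5, 3, 1),
    MammoRecord(4, 43, 1, 1, None, 1),   # missing density
    MammoRecord(5, 58, 4, 5, 3, 1),
    MammoRecord(4, 28, 1, 1, 3, 0),
    MammoRecord(55, 74, 1, 5, 3, 1),     # BI-RADS typo outside 1-6
    MammoRecord(4, 63, 1, 1, 3, 0),
]

PATH = Path(tempfile.gettempdir()) / "synthetic_mammo.csv"
write_mammo_csv(records, PATH)

parsed, missing = read_mammo_csv(PATH)
print(f"parsed {len(parsed)} records")
print("missing per field:", {k: v for k, v in missing.items() if v})

table = clean(parsed)
print(f"after cleaning: {table.n_samples} records "
      f"({len(parsed) - table.n_samples} dropped), "
      f"{int(table.targets.sum())} malignant")
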