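"""Quantify gene-modification rates from SURVEYOR cleavage bands.

Given gel band intensities (uncleaved parent + cleavage products), the
fraction cleaved is converted to % genes modified via
(1 - sqrt(1 - fraction cleaved)) x 100; the square root accounts for
heteroduplex formation between modified and unmodified strands.
"""

from crisprindel.surveyor import (SurveyorMeasurement, fraction_cleaved,
                                  percent_modified)

lanes = {
    "gRNA-A": SurveyorMeasurement(parent_intensity=80.0,
                                  cleaved_intensities=[10.0, 10.0]),
    "gRNA-B": SurveyorMeasurement(parent_intensity=81.0,
                                  cleaved_intensities=[12.0, 7.0],
                                  background=0.0),
    "mock": SurveyorMeasurement(parent_intensity=100.0,
                                cleaved_intensities=[]),
}

print("lane      fraction_cleaved   % genes modified")
for lane, m in lanes.items():
    fc = fraction_cleaved(m)
    print(f"{lane:8s}  {fc:16.3f}   {percent_modified(fc):16.2f}")
# A fully uncleaved lane maps to 0% modified; fc = 0.19 would map to
# exactly 10% because 1 - sqrt(0.81) = 0.1.
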