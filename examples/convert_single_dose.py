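"""Translate one mouse xenograft dose to a predicted human dose.

A mouse efficacious dose in mg/kg is scaled by body surface area
(×3 into mg/m², ÷37 into human mg/kg); for antibodies above 100 kDa
the mg/kg value carries over unchanged instead.
"""

from xenodose import (
    bsa_predict_human_dose,
    bw_predict_human_dose,
    mrsd_from_hed,
    select_method,
)

mouse_dose = 37.0  # mg/kg, Day-1 total in the xenograft study

hed = bsa_predict_human_dose(mouse_dose)
print(f"mouse dose:            {mouse_dose:g} mg/kg")
print(f"BSA-scaled human dose: {hed:g} mg/kg   (x3/37)")
print(f"starting dose (MRSD):  {mrsd_from_hed(hed, 10):g} mg/kg   (10x margin)")

# method selection by molecular weight
for name, mw in [("blinatumomab-like bispecific", 54.1), ("intact IgG", 150.0)]:
    method = select_method(mw)
    predicted = (bsa_predict_human_dose(2.0) if method.value == "bsa"
                 else bw_predict_human_dose(2.0))
    print(f"{name} ({mw:g} kDa): method={method.value}, "
          f"2 mg/kg mouse -> {predicted:.3g} mg/kg human")

# The 37 mg/kg mouse dose maps to exactly 3 mg/kg in human; dividing by
# the 10x safety factor gives a 0.3 mg/kg starting dose. The bispecific
# falls below the 100 kDa cutoff and is scaled by BSA; the IgG is not.
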