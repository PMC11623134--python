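"""Fit the three level encodings on one tiny table and print their rank maps.

The integer encoding ignores the response; the two target-based encodings
order levels by how their observed class mix relates to the response, which
is exactly what makes them leak target information when fitted on data that
is later treated as held out.
"""

from leakyforest import (
    fit_integer_encoding,
    fit_target_encoding_multiclass,
    fit_target_encoding_twoclass,
)

x = ["apple", "berry", "cherry", "apple", "berry", "cherry", "apple", "berry"]
y2 = ["no", "yes", "yes", "no", "yes", "no", "no", "yes"]       # two classes
y3 = ["c1", "c2", "c3", "c1", "c2", "c3", "c2", "c2"]           # three classes

print("alphabetical :", dict(fit_integer_encoding(x).ranks))
print("two-class    :", dict(fit_target_encoding_twoclass(x, y2).ranks),
      "(ascending share of 'yes')")
print("multiclass   :", dict(fit_target_encoding_multiclass(x, y3).ranks),
      "(ascending 1st-PC projection of class profiles)")
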