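"""Reconstruct and minimize the Boolean functions of each electrode.

At a chosen transition step t the machine's responses form a map
g : {0,1}^6 -> {0,1}^6 (input string -> state).  Bit e of g is electrode
e's Boolean function of the six input bits; inputs that produced no t-th
response are don't-cares.  Quine–McCluskey minimization with Petrick
cover selection yields the disjunctive normal form.
"""

import actinmachine as am
from actinmachine.boolmin import dnf_to_string, minimize_dnf, table_from_g

# a hand-made response map at k=3 for illustration:
# inputs 1..5 observed, 6..7 unobserved (don't-cares)
g = {1: 0b001, 2: 0b011, 3: 0b001, 4: 0b100, 5: 0b101}

for e in range(3):
    table = table_from_g(g, e, 3)
    dnf = minimize_dnf(table)
    print(f"f{e}(x0,x1,x2) = {dnf_to_string(dnf)}")

print("\nf_e is electrode e's response bit as a function of the input bits;")
print("don't-care rows let the minimizer merge terms it never has to defend.")
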