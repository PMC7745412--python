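"""Annotate RNA secondary structures with six-letter loop types.

A dot-bracket string is reduced to one structural-context letter per
position: S stem, H hairpin loop, I internal loop/bulge, M multiloop,
F dangling start, T dangling end.  These shape strings are the structure
input of the classifier.
"""

from kebind import parse_dot_bracket, shapes_from_dot_bracket

structures = [
    "..((((...))))..",          # hairpin with dangling ends
    "((..((...))..))",          # internal loop
    "((.((...)).((...)).))",    # multiloop with two branch helices
]
for db in structures:
    shape = shapes_from_dot_bracket(db)
    paired = parse_dot_bracket(db).n_paired
    print(db)
    print(shape, f"   ({paired} paired positions -> {shape.count('S')} S)")
    print()
# Every paired position is S; unpaired positions are classified by the loop
# enclosing them (0 enclosed branches = H, 1 = I, >= 2 = M) or F/T outside.
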