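"""Writing and running programs in the language of geometry.

Programs move a point over the 8 vertices of an octagon using rotations
(+1, +2, -1, -2), axial reflections (H, V, A, B), the point symmetry P,
plain repetition [x]^n and repetition-with-variation [x]^n<v>.  The cost of
a program is its description length: 2 per instruction, ceil(log2 n) per
repetition, and the transform's cost plus a flag for a variation.
"""

from geomlang import Atom, Repeat, RepeatVar, emit, from_text, program_cost, to_text

# A square is four +2 steps; written with repetition it is [+2]^4.
square = Repeat(Atom("+2"), 4)
print("square from anchor 6:", emit(square, 6))
print("cost of [+2]^4:", program_cost(square))

# Two squares: draw three sides, then redraw the whole figure with its
# starting point rotated by one vertex.
two_squares = RepeatVar(Repeat(Atom("+2"), 3), 2, "+1")
print("two squares:", emit(two_squares, 0))
print(f"cost of {to_text(two_squares)}:", program_cost(two_squares))

# The notation round-trips losslessly.
text = "[[H]^2<V>]^2<+2>"
prog = from_text(text)
print(f"{text} emits {emit(prog, 0)} at cost {program_cost(prog)}")

# Expected output: the square visits (0,2,4,6); two_squares emits
# (0,2,4,6,1,3,5,7) at cost 8 -- the figure costs 4 and the variation 4
# more -- and the nested rectangle program emits 8 vertices at cost 10.
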