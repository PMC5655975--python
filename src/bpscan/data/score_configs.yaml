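# Named members of the S* scoring family.
#
# Each entry gives the weight vector P = (P1, P2, P3) and exponent vector
# Q = (Q1, Q2, Q3); term j applies to the hexamer with heptamer position
# k = j + 4 deleted (k = 5, 6, 7).  Two members are canonical:
#   score0 — P = 0: the energy term vanishes and S* is the plain PSSM score;
#   score8 — only the branch-site term is active (P = (0,1,0), Q2 = 1), the
#            operating point used for prediction by default.
# The remaining members sweep the subsets of {5,6,7} at two exponent
# settings (Q = 0.5 for score1-7, Q = 1 for score8-14).  Edit freely; the
# file, not the code, defines the family.
score0:  {P: [0, 0, 0], Q: [0, 0, 0]}
score1:  {P: [0, 1, 0], Q: [0.5, 0.5, 0.5]}
score2:  {P: [1, 0, 0], Q: [0.5, 0.5, 0.5]}
score3:  {P: [0, 0, 1], Q: [0.5, 0.5, 0.5]}
score4:  {P: [1, 1, 0], Q: [0.5, 0.5, 0.5]}
score5:  {P: [0, 1, 1], Q: [0.5, 0.5, 0.5]}
score6:  {P: [1, 0, 1], Q: [0.5, 0.5, 0.5]}
score7:  {P: [1, 1, 1], Q: [0.5, 0.5, 0.5]}
score8:  {P: [0, 1, 0], Q: [1, 1, 1]}
score9:  {P: [1, 0, 0], Q: [1, 1, 1]}
score10: {P: [0, 0, 1], Q: [1, 1, 1]}
score11: {P: [1, 1, 0], Q: [1, 1, 1]}
score12: {P: [0, 1, 1], Q: [1, 1, 1]}
score13: {P: [1, 0, 1], Q: [1, 1, 1]}
score14: {P: [1, 1, 1], Q: [1, 1, 1]}
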