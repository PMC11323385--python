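O=[N+]([O-])C1CCCCC1O ex0
O=C(O)c1cccc([N+](=O)[O-])n1 ex1
O=C(O)c1ccccc1O ex2
Cc1cccc(-c2ccc(O)cc2)c1 ex3
O=[N+]([O-])c1cccc(-c2ccccc2O)c1 ex4
CC(=O)Nc1ccc(O)cn1 ex5
O=[N+]([O-])c1cccc(-c2ccccc2[N+](=O)[O-])c1 ex6
CC(=O)Nc1ccccc1NC(C)=O ex7
Cc1cc(-c2ccccc2)cc([N+](=O)[O-])c1 ex8
Cc1ccc(C(=O)O)nc1 ex9
CC(=O)Nc1cccc(-c2ccc(C)cc2)c1 ex10
CC1CCCC(O)C1 ex11
CC(=O)Nc1cccc(-c2ccccc2NC(C)=O)c1 ex12
O=[N+]([O-])c1ccc([N+](=O)[O-])nc1 ex13
O=C(O)c1cccc(-c2ccccc2C(=O)O)c1 ex14
O=[N+]([O-])c1ccccc1O ex15
CC(=O)NC1CCCC([N+](=O)[O-])C1 ex16
O=C(O)c1ccc([N+](=O)[O-])nc1 ex17
CC(=O)NC1CCCCC1C(=O)O ex18
O=C(O)c1ccccc1C(=O)O ex19
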