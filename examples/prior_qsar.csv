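smiles,label
O=C(O)C1CCCCC1O,1
c1ccccc1,1
CC(=O)Nc1ccc(C(=O)O)nc1,1
O=[N+]([O-])c1ccc(-c2cccc([N+](=O)[O-])c2)cc1,0
Cc1cccc(-c2ccccc2C)c1,1
O=[N+]([O-])C1CCCCC1,0
CC(=O)Nc1cccc(-c2ccccc2O)c1,1
CC(=O)Nc1ccccc1C,1
Cc1cccnc1,1
O=[N+]([O-])C1CCCCC1[N+](=O)[O-],0
Cc1ccc(-c2ccccc2)cc1,1
O=C(O)c1ccccc1,1
CC(=O)Nc1cccc(C(=O)O)c1,1
O=[N+]([O-])c1cccc(-c2ccccc2O)c1,0
O=C(O)c1cc(-c2ccccc2)cc([N+](=O)[O-])c1,0
CC(=O)Nc1cccnc1,1
Cc1cc([N+](=O)[O-])ccn1,0
O=C(O)c1ccccn1,1
O=C(O)c1ccncc1,1
CC(=O)Nc1ccccc1NC(C)=O,1
O=[N+]([O-])c1cccc(-c2ccccc2[N+](=O)[O-])c1,0
O=[N+]([O-])c1ccccc1O,0
CC(=O)Nc1ccc([N+](=O)[O-])nc1,0
CC(=O)Nc1cccc(-c2ccccc2C(=O)O)c1,1
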