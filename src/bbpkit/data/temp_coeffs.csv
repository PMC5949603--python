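compound,proton,coefficient,bold,determined
1,Leu1-HN,7.3,False,True
2,Leu1-HN,8.1,False,True
3,Leu1-HN,3.7,True,True
4,Leu1-HN,7.7,False,True
5,Leu1-HN,7.8,False,True
6,Leu1-HN,8.5,False,True
7,Leu1-HN,6.8,False,True
8,Leu1-HN,7.8,False,True
9,Leu1-HN,7.2,False,True
1,Gly2-HN,7.9,False,True
2,Gly2-HN,7.7,False,True
3,Gly2-HN,4.4,False,True
4,Gly2-HN,6.8,False,True
5,Gly2-HN,7.0,False,True
6,Gly2-HN,7.9,False,True
7,Gly2-HN,6.2,False,True
8,Gly2-HN,7.6,False,True
9,Gly2-HN,7.9,False,True
1,Lys3-HN,8.8,False,True
2,Lys3-HN,3.1,True,True
3,Lys3-HN,2.4,True,True
4,Lys3-HN,2.1,True,True
5,Lys3-HN,1.3,True,True
6,Lys3-HN,2.8,True,True
7,Lys3-HN,1.4,True,True
8,Lys3-HN,2.0,True,True
9,Lys3-HN,1.6,True,True
1,Phe4-HN,6.6,False,True
2,Phe4-HN,7.2,False,True
3,Phe4-HN,5.2,False,True
4,Phe4-HN,5.3,False,True
5,Phe4-HN,10.0,False,True
6,Phe4-HN,8.0,False,True
7,Phe4-HN,6.3,False,True
8,Phe4-HN,8.8,False,True
9,Phe4-HN,9.2,False,True
1,Glu6-HN,1.7,True,True
2,Glu6-HN,2.3,True,True
3,Glu6-HN,-1.0,True,True
4,Glu6-HN,1.2,True,True
5,Glu6-HN,1.2,True,True
6,Glu6-HN,1.2,True,True
7,Glu6-HN,1.8,True,True
8,Glu6-HN,1.5,True,True
9,Glu6-HN,7.2,False,True
1,Ala7-HN,3.0,True,True
2,Ala7-HN,7.6,False,True
3,Ala7-HN,0.3,True,True
4,Ala7-HN,1.4,True,True
5,Ala7-HN,9.6,False,True
6,Ala7-HN,6.2,False,True
7,Ala7-HN,9.9,False,True
8,Ala7-HN,9.0,False,True
9,Ala7-HN,8.3,False,True
1,Lys3-HNe,6.6,False,True
2,Lys3-HNe,7.3,False,True
3,Lys3-HNe,,False,False
4,Lys3-HNe,4.3,False,True
5,Lys3-HNe,6.6,False,True
6,Lys3-HNe,6.6,False,True
7,Lys3-HNe,,False,False
8,Lys3-HNe,6.5,False,True
9,Lys3-HNe,2.0,True,True
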