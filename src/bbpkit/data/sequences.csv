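id,notation,flags,kind,source,printed_formula,formula_consistent,printed_mz,mz_consistent
1,l1 G k2 f P E1 a2,,bicycle,table1,C36H52N8O8,True,[M+H]+=725.40;[M+Na]+=747.38,True
2,l1 G k2 f P E1 A2,,bicycle,table1,C36H52N8O8,True,[M+H]+=725.40;[M+Na]+=747.38,True
3,l1 G k2 F P E1 a2,,bicycle,table1,C36H52N8O8,True,[M+H]+=725.40;[M+Na]+=747.38,True
4,L1 G k2 f P E1 a2,,bicycle,table1,C36H52N8O8,True,[M+H]+=725.40;[M+Na]+=747.38,True
5,l1 G k2 F P E1 A2,,bicycle,table1,C36H52N8O8,True,[M+H]+=725.40;[M+Na]+=747.38,True
6,L1 G k2 f P E1 A2,,bicycle,table1,C36H52N8O8,True,[M+H]+=725.40;[M+Na]+=747.38,True
7,L1 G k2 F P E1 a2,,bicycle,table1,C36H52N8O8,True,[M+H]+=725.40;[M+Na]+=747.38,True
8,L1 G k2 F P E1 A2,,bicycle,table1,C36H52N8O8,True,[M+H]+=725.40;[M+Na]+=747.38,True
9,L1 G K2 F P E1 A2,,bicycle,table1,C36H52N8O8,True,[M+H]+=725.40;[M+Na]+=747.38,True
10,l1 G k2 y P E1 a2,,bicycle,table1,C36H52N8O9,True,[M+H]+=741.39;[M+Na]+=763.37;[M+K]+=779.35;[M+K+H]2+=390.17,True
11,l1 G k2 y P E1 A2,,bicycle,table1,C36H52N8O8,False,[M+H]+=741.39,True
12,l1 G k2 Y P E1 a2,,bicycle,table1,C36H52N8O8,False,[M+H]+=741.39,True
13,L1 G k2 y P E1 a2,,bicycle,table1,C36H52N8O8,False,[M+H]+=741.39,True
14,l1 G k2 Y P E1 A2,,bicycle,table1,C36H52N8O8,False,[M+H]+=741.39,True
15,L1 G k2 y P E1 A2,,bicycle,table1,C36H52N8O9,True,[M+H]+=741.39;[M+Na]+=763.37,True
16,L1 G k2 Y P E1 a2,,bicycle,table1,C36H52N8O8,False,[M+H]+=741.39,True
17,L1 G k2 Y P E1 A2,,bicycle,table1,C36H52N8O8,False,[M+H]+=741.39,True
18,L1 G K2 Y P E1 A2,,bicycle,table1,C36H52N8O8,False,[M+H]+=741.39,True
19,k1 G k2 f P E1 a2,,bicycle,table1,C36H53N9O8,True,[M+H]+=740.41;[M+Na]+=762.39;[M+K+H]2+=389.68,True
20,l1 S k2 f P E1 a2,,bicycle,table1,C37H54N8O9,True,[M+H]+=755.41;[M+Na]+=777.39;[M+K+H]2+=397.18;[M+K]+=793.36;[M+Na+H]2+=389.19,True
21,l1 G k2 f K E1 a2,,bicycle,table1,C37H57N9O8,True,[M+H]+=756.44;[M+Na]+=778.42,True
22,k1 G k2 e P E1 c2,,bicycle,table1,C32H51N9O10S,True,[M+H]+=754.36;[M+Na]+=776.34;[M+K+H]2+=396.65,True
23,K1 G k2 f P E1 A2,,bicycle,table1,C36H53N9O8,True,[M+H]+=740.41;[M+2H]2+=370.71,True
24,L1 S k2 f P E1 A2,,bicycle,table1,C37H54N8O9,True,[M+H]+=755.41;[M+Na]+=777.39,True
25,L1 G k2 f K E1 A2,,bicycle,table1,C37H57N9O8,True,[M+H]+=756.44;[M+Na]+=778.42,True
26,K1 G k2 e P E1 C2,,bicycle,table1,C37H53N9O9,False,[M+H]+=754.35,True
1-mono,l1 G k f P E1 a,,mono,exp,C36H54N8O9,True,[M+H]+=743.41,True
2-mono,l1 G k f P E1 A,,mono,exp,C36H54N8O9,True,[M+H]+=743.41,True
3-mono,l1 G k F P E1 a,,mono,exp,C36H54N8O9,True,[M+H]+=743.41,True
4-mono,L1 G k f P E1 a,,mono,exp,C36H54N8O9,True,[M+H]+=743.41,True
5-mono,l1 G k F P E1 A,,mono,exp,C36H54N8O9,True,[M+H]+=743.41,True
6-mono,L1 G k f P E1 A,,mono,exp,C36H54N8O9,True,[M+H]+=743.41,True
7-mono,L1 G k F P E1 a,,mono,exp,C36H54N8O9,True,[M+H]+=743.41,True
8-mono,L1 G k F P E1 A,,mono,exp,C36H54N8O9,True,[M+H]+=743.41,True
9-mono,L1 G K F P E1 A,,mono,exp,C36H54N8O9,True,[M+H]+=743.41,True
11-mono,l1 G k y P E1 A,,mono,exp,C36H54N8O10,True,[M+H]+=759.40,True
12-mono,l1 G k Y P E1 a,,mono,exp,C36H54N8O10,True,[M+H]+=759.40,True
13-mono,L1 G k y P E1 a,,mono,exp,C36H54N8O10,True,[M+H]+=759.40,True
14-mono,l1 G k Y P E1 A,,mono,exp,C36H54N8O10,True,[M+H]+=759.40,True
16-mono,L1 G k Y P E1 a,,mono,exp,C36H54N8O10,True,[M+H]+=759.40,True
17-mono,L1 G k Y P E1 A,,mono,exp,C36H54N8O10,True,[M+H]+=759.40,True
18-mono,L1 G K Y P E1 A,,mono,exp,C36H54N8O10,True,[M+H]+=759.40,True
27c,K2 E1 K w z2 W K1 G,amide,bicycle,table3,C52H72N14O10S,True,[M+H]+=1085.53,True
27x,K2 E1 K w z2 W K1 G B G G K(biot),amide,bicycle,table3,C88H117N21O17S2,True,[M+H]+=1804.85,True
27s,K2 E1 K w z2 W K1 G F G G K(biot),amide,bicycle,table3,C81H113N21O16S2,True,[M+H]+=1700.82,True
28c,R2 E1 R f z2 F K1 G,amide,bicycle,table3,C48H70N16O10S,True,[M+H]+=1063.52,True
28x,R2 E1 R f z2 F K1 G B G G K(biot),amide,bicycle,table3,C84H115N23O17S2,True,[M+2H]2+=892.42,False
28s,R2 E1 R f z2 F K1 G F G G K(biot),amide,bicycle,table3,C77H111N23O16S2,True,[M+2H]2+=839.91,True
29c,E2 E1 E f z2 F K1 G,amide,bicycle,table3,C46H60N10O14S,True,[M+H]+=1009.41,True
29x,E2 E1 E f z2 F K1 G B G G K(biot),amide,bicycle,table3,C82H105N17O21S2,True,[M+2H]2+=864.86,True
29s,E2 E1 E f z2 F K1 G F G G K(biot),amide,bicycle,table3,C75H101N17O20S2,True,[M+H]+=1624.69,True
30,Mel1 G k2 f P E1 a2,,bicycle,table4,C37H54N8O8,True,[M+H]+=739.41,True
31,l1 MeG k2 f P E1 a2,,bicycle,table4,C37H54N8O8,True,[M+H]+=739.41,True
32,l1 G k2 Mef P E1 a2,,bicycle,table4,C37H54N8O9,False,[M+H]+=739.41,True
33,Mel1 MeG k2 f P E1 a2,,bicycle,table4,C38H56N8O8,True,[M+H]+=753.43,True
34,Mel1 G k2 Mef P E1 a2,,bicycle,table4,C38H56N8O8,True,[M+H]+=753.43,True
35,l1 MeG k2 Mef P E1 a2,,bicycle,table4,C38H56N8O8,True,[M+Na]+=775.41,True
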