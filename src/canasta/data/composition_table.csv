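code,name,group,energy_kcal_100g,protein_g_100g,fat_g_100g,carb_g_100g
F001,arroz pilado,cereals,358,7.8,0.7,78.8
F002,fideos tallarin,cereals,350,11.0,1.3,72.0
F003,avena hojuelas,cereals,380,13.3,6.3,66.3
F004,harina de trigo,cereals,354,10.5,2.0,74.0
F005,quinua,cereals,351,13.6,5.8,66.6
F006,pan frances,cereals,277,8.8,0.6,58.5
F007,azucar rubia,sugars,380,0.4,0.1,97.4
F008,azucar blanca,sugars,384,0.0,0.0,99.2
F009,chancaca,sugars,351,0.5,0.1,90.0
F010,miel de abeja,sugars,304,0.3,0.0,82.0
F011,conserva de pescado en agua,meats,116,25.0,1.5,0.0
F012,conserva de pescado en aceite,meats,190,24.0,10.0,0.0
F013,anchoveta en conserva,meats,160,20.0,8.5,0.5
F014,pollo carne,meats,170,18.2,10.2,0.0
F015,carne de res,meats,105,21.3,1.6,0.0
F016,aceite vegetal,oils,884,0.0,100.0,0.0
F017,aceite de oliva,oils,884,0.0,100.0,0.0
F018,margarina,oils,717,0.2,80.5,0.4
F019,leche evaporada entera,dairy,134,6.8,7.6,10.0
F020,leche en polvo entera,dairy,496,26.3,26.7,38.4
F021,queso fresco,dairy,264,17.5,20.1,3.3
F022,yogur natural,dairy,62,3.5,3.3,4.7
F023,lenteja,legumes,336,23.2,1.1,60.1
F024,frijol canario,legumes,330,21.8,1.6,61.0
F025,arveja seca partida,legumes,340,21.7,3.2,61.0
F026,haba seca,legumes,338,25.1,2.2,58.3
F027,garbanzo,legumes,364,19.3,6.0,61.0
F028,platano de seda,fruits,89,1.1,0.3,22.8
F029,naranja,fruits,47,0.9,0.1,11.7
F030,manzana,fruits,52,0.3,0.2,13.8
F031,mandarina,fruits,53,0.8,0.3,13.3
F032,huevo de gallina,eggs,141,12.6,9.5,0.7
F033,cebolla,vegetables,40,1.1,0.1,9.3
F034,zanahoria,vegetables,41,0.9,0.2,9.6
F035,tomate,vegetables,18,0.9,0.2,3.9
F036,zapallo,vegetables,26,1.0,0.1,6.5
F037,papa blanca,tubers,77,2.0,0.1,17.5
F038,camote,tubers,86,1.6,0.1,20.1
F039,yuca,tubers,160,1.4,0.3,38.1
F040,olluco,tubers,62,1.1,0.1,14.3
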